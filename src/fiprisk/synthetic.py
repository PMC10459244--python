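"""Synthetic input generation for end-to-end testing of the pipeline.

The original assessment draws on three external Taiwanese databases
(per-sample residue surveillance, household-registry demographics with
body-weight surveys, and the national food-consumption database).  This
module emulates their statistical structure from published summary
statistics: per-category sample totals, detect counts and detect-only
moments at a 0.002 ppm detection limit for residues, plus invented but
realistic demographic and intake tables.  Every generator is a pure function
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .doseresponse import DichotomousModel, DoseResponseData
from .exposure import lognormal_params_from_moments
from .residues import CensoredResidueDataset

__all__ = [
    "CategorySpec",
    "RESIDUE_SPECS",
    "GeneratedResidueDataset",
    "calibrate_gm_gsd_to_spec",
    "generate_residue_dataset",
    "PopulationSpec",
    "default_population_spec",
    "generate_population_inputs",
    "generate_dose_response",
    "write_input_bundle",
]


@dataclass(frozen=True)
class CategorySpec:
    """Summary statistics of one food category's residue surveillance."""

    category: str
    n_total: int
    n_detect: int
    detect_mean: float
    detect_sd: float | None
    detection_limit: float = 0.002

    def __post_init__(self) -> None:
        if self.n_detect > self.n_total or self.n_detect < 1:
            raise ValueError("need 1 <= n_detect <= n_total")
        if self.detect_mean <= 0:
            raise ValueError("detect_mean must be positive")

    @property
    def censoring_rate(self) -> float:
        return 1.0 - self.n_detect / self.n_total


# Published surveillance summaries for the 11 food categories
# (total samples, detects, detect-only mean and SD in ppm, DL 0.002 ppm).
RESIDUE_SPECS: dict[str, CategorySpec] = {
    s.category: s
    for s in [
        CategorySpec("LF", 2042, 1, 0.003, None),
        CategorySpec("SF", 923, 1, 0.002, None),
        CategorySpec("CF", 1046, 1, 0.014, None),
        CategorySpec("CB", 1265, 3, 0.229, 0.138),
        CategorySpec("SV", 6974, 42, 0.115, 0.328),
        CategorySpec("FV", 2556, 9, 0.018, 0.025),
        CategorySpec("LV", 1867, 8, 0.010, 0.005),
        CategorySpec("RV", 1760, 44, 0.013, 0.013),
        CategorySpec("DB", 229, 5, 0.006, 0.004),
        CategorySpec("CG", 40, 2, 0.014, 0.011),
        CategorySpec("SP", 858, 4, 0.051, 0.027),
    ]
}


def _conditional_mean_above(mu: float, sdlog: float, dl: float) -> float:
    """E[Y | Y > dl] for Y ~ lognormal(mu, sdlog)."""
    z = (np.log(dl) - mu) / sdlog
    tail = stats.norm.sf(z)
    return float(np.exp(mu + 0.5 * sdlog**2) * stats.norm.sf(z - sdlog) / tail)


def calibrate_gm_gsd_to_spec(spec: CategorySpec) -> tuple[float, float]:
    """Solve for lognormal (GM, GSD) matching a category's summary row.

    With censoring present the solution satisfies exactly
    ``P(Y < DL) = censoring_rate`` and ``E[Y | Y > DL] = detect_mean``; the
    detect SD is then implied rather than imposed (the three summary
    statistics overdetermine the two lognormal parameters).  With zero
    censoring the detect moments are unconditional and are moment-matched
    directly.
    """
    if spec.detect_sd is not None and spec.detect_sd == 0 and spec.n_detect >= 2:
        raise ValueError(f"{spec.category}: degenerate detect_sd = 0 with several detects")
    c = spec.censoring_rate
    if c <= 0:
        if spec.detect_sd is None:
            raise ValueError(f"{spec.category}: need detect_sd when nothing is censored")
        p = lognormal_params_from_moments(spec.detect_mean, spec.detect_sd)
        return float(np.exp(p.meanlog)), float(np.exp(p.sdlog))
    if spec.detect_mean < spec.detection_limit:
        raise ValueError(
            f"{spec.category}: detect mean {spec.detect_mean} below the "
            f"detection limit {spec.detection_limit}; no lognormal matches"
        )
    # a detect mean printed at the DL itself (rounded single detect) has no
    # attainable exact solution; target a small margin above the limit
    target_mean = max(spec.detect_mean, 1.05 * spec.detection_limit)
    z_c = stats.norm.ppf(c)

    def gap(sdlog: float) -> float:
        mu = np.log(spec.detection_limit) - sdlog * z_c
        return _conditional_mean_above(mu, sdlog, spec.detection_limit) - target_mean

    lo, hi = 1e-6, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"{spec.category}: conditional mean not attainable by any GSD in range")
    sdlog = brentq(gap, lo, hi, xtol=1e-12)
    mu = np.log(spec.detection_limit) - sdlog * z_c
    return float(np.exp(mu)), float(np.exp(sdlog))


@dataclass(frozen=True)
class GeneratedResidueDataset:
    """A synthetic censored dataset together with its generating truth."""

    dataset: CensoredResidueDataset
    true_gm: float
    true_gsd: float
    seed: int
    all_values: np.ndarray

    def truth_dict(self) -> dict:
        return {
            "category": self.dataset.category,
            "true_gm": self.true_gm,
            "true_gsd": self.true_gsd,
            "seed": self.seed,
        }


def generate_residue_dataset(
    spec: CategorySpec,
    true_gm: float | None = None,
    true_gsd: float | None = None,
    seed: int = 0,
) -> GeneratedResidueDataset:
    """Draw a per-sample residue dataset from a known lognormal.

    Defaults to the (GM, GSD) calibrated to the spec's summary row; values
    below the detection limit are flagged censored, so the realized detect
    count fluctuates binomially around the spec's.
    """
    if true_gm is None or true_gsd is None:
        true_gm, true_gsd = calibrate_gm_gsd_to_spec(spec)
    if true_gm <= 0 or true_gsd < 1:
        raise ValueError("need true_gm > 0 and true_gsd >= 1")
    sdlog = np.log(true_gsd)
    # deterministic retry on sub-streams: a dataset needs >= 1 detect, and at
    # extreme censoring a draw can produce none
    for attempt in range(100):
        rng = np.random.default_rng([seed, attempt])
        if sdlog == 0:
            values = np.full(spec.n_total, true_gm)
        else:
            values = rng.lognormal(np.log(true_gm), sdlog, size=spec.n_total)
        if np.any(values >= spec.detection_limit):
            break
    else:
        raise ValueError(f"{spec.category}: no detects after 100 attempts; truth too far below DL")
    detects = values[values >= spec.detection_limit]
    n_cen = int(spec.n_total - detects.size)
    dataset = CensoredResidueDataset(
        category=spec.category,
        values=detects,
        n_cen=n_cen,
        detection_limit=spec.detection_limit,
    )
    return GeneratedResidueDataset(dataset, float(true_gm), float(true_gsd), seed, values)


@dataclass(frozen=True)
class PopulationSpec:
    """Invented demographic/intake structure emulating the survey databases."""

    ages: tuple[int, int] = (0, 100)
    male_fraction: float = 0.494
    n_population: int = 23_000_000
    bw_sd_fraction: float = 0.15
    ub_over_lb: float = 2.0  # consumer-only intake inflation over general population

    def __post_init__(self) -> None:
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")


def _bw_mean(age: np.ndarray, sex: str) -> np.ndarray:
    """Smooth body-weight growth curve (kg): rapid growth to an adult plateau."""
    adult = 68.0 if sex == "male" else 56.0
    bw = 3.4 + (adult - 3.4) * (age / (age + 4.0)) ** 1.3
    return np.where(age >= 66, bw * 0.96, bw)


def _age_weights(ages: np.ndarray) -> np.ndarray:
    """Plausible age pyramid: flat through mid-life, tapering after 65."""
    w = np.ones_like(ages, dtype=float)
    old = ages > 65
    w[old] = np.exp(-(ages[old] - 65) / 12.0)
    return w / w.sum()


# per-category LB (general population) intake means, g/day — invented but
# ordered like a plausible diet (vegetables and fruit dominate, spices trace)
_LB_INTAKE = {
    "LF": 45.0, "SF": 30.0, "CF": 25.0, "CB": 35.0, "SV": 60.0, "FV": 40.0,
    "LV": 15.0, "RV": 50.0, "DB": 20.0, "CG": 30.0, "SP": 1.0,
}


def default_population_spec() -> PopulationSpec:
    return PopulationSpec()


def generate_population_inputs(
    spec: PopulationSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit (demographics, intakes) tables in the exposure-stage schemas."""
    spec = spec or default_population_spec()
    rng = np.random.default_rng(seed)
    ages = np.arange(spec.ages[0], spec.ages[1] + 1)
    weights = _age_weights(ages)
    rows = []
    for sex, frac in (("male", spec.male_fraction), ("female", 1 - spec.male_fraction)):
        bw = _bw_mean(ages, sex)
        counts = np.round(spec.n_population * frac * weights).astype(int)
        for a, c, m in zip(ages, counts, bw):
            rows.append(
                {
                    "age": int(a),
                    "sex": sex,
                    "count": int(c),
                    "bw_mean": round(float(m), 2),
                    "bw_sd": round(float(spec.bw_sd_fraction * m), 2),
                }
            )
    demographics = pd.DataFrame(rows)

    intake_rows = []
    for cat, lb_mean in _LB_INTAKE.items():
        jitter = 1.0 + 0.1 * rng.standard_normal()
        lb = max(lb_mean * jitter, 0.1)
        ub = lb * spec.ub_over_lb
        intake_rows.append({"category": cat, "scenario": "LB", "mean": round(lb, 2), "sd": round(lb, 2)})
        intake_rows.append({"category": cat, "scenario": "UB", "mean": round(ub, 2), "sd": round(0.8 * ub, 2)})
    intakes = pd.DataFrame(intake_rows)
    return demographics, intakes


def generate_dose_response(
    model: DichotomousModel,
    params: np.ndarray,
    doses: np.ndarray,
    n_per_dose: int | np.ndarray,
    seed: int = 0,
) -> DoseResponseData:
    """Binomial incidences drawn from a known dose-response curve."""
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if not model.in_bounds(params).all():
        raise ValueError("parameters outside the model's admissible bounds")
    doses = np.asarray(doses, dtype=float)
    n = np.broadcast_to(np.asarray(n_per_dose, dtype=int), doses.shape)
    p = model.prob(params, doses)[0]
    rng = np.random.default_rng(seed)
    incidence = rng.binomial(n, p)
    return DoseResponseData(doses=doses, n=n.copy(), incidence=incidence)


def write_input_bundle(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full synthetic input bundle (residues, demographics,
    intakes, dose-response) as CSV files and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    residue_rows = []
    truth_rows = []
    for i, (cat, spec) in enumerate(RESIDUE_SPECS.items()):
        gen = generate_residue_dataset(spec, seed=int(rng.integers(2**31 - 1)))
        truth_rows.append(gen.truth_dict())
        for v in gen.dataset.values:
            residue_rows.append(
                {"category": cat, "value": v, "censored": 0, "detection_limit": spec.detection_limit}
            )
        # non-detects carry no value, only the flag and the DL
        residue_rows.extend(
            {"category": cat, "value": "", "censored": 1, "detection_limit": spec.detection_limit}
            for _ in range(gen.dataset.n_cen)
        )
    paths = {}
    residues = pd.DataFrame(residue_rows)
    paths["residues"] = outdir / "residues.csv"
    residues.to_csv(paths["residues"], index=False)
    paths["residue_truth"] = outdir / "residue_truth.csv"
    pd.DataFrame(truth_rows).to_csv(paths["residue_truth"], index=False)

    demographics, intakes = generate_population_inputs(seed=seed)
    paths["demographics"] = outdir / "demographics.csv"
    demographics.to_csv(paths["demographics"], index=False)
    paths["intakes"] = outdir / "intakes.csv"
    intakes.to_csv(paths["intakes"], index=False)

    from .doseresponse import FIPRONIL_CONVULSION

    dr = pd.DataFrame(
        {
            "dose": FIPRONIL_CONVULSION.doses,
            "n": FIPRONIL_CONVULSION.n,
            "incidence": FIPRONIL_CONVULSION.incidence,
        }
    )
    paths["dose_response"] = outdir / "dose_response.csv"
    dr.to_csv(paths["dose_response"], index=False)
    return paths
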