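"""Monte Carlo dietary exposure simulation for a stratified population.

Simulates individuals from age x sex demographic strata, assigns body weight
and per-category food intakes from truncated normal distributions, draws
residue concentrations from the reconstructed posterior lognormals and
computes each individual's aggregate chronic dose

    exposure_j = sum_i intake_{i,j} [g/day] * residue_{i,j} [mg/kg]
                 / (bodyweight_j [kg] * 1000)     [mg/kg bw/day]

under two intake scenarios: LB (general population, includes non-consumers)
and UB (consumer-only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LognormalParams",
    "DemographicStratum",
    "IntakeSpec",
    "lognormal_params_from_moments",
    "sample_truncated_normal",
    "allocate_population",
    "aggregate_exposure",
    "run_exposure_scenario",
    "summarize_exposure",
    "load_demographics",
    "load_intakes",
    "AGE_GROUPS",
]

# reporting age groups: label -> (low, high) inclusive
AGE_GROUPS: dict[str, tuple[int, int]] = {
    "all": (0, 200),
    "0-2": (0, 2),
    "3-5": (3, 5),
    "6-11": (6, 11),
    "12-15": (12, 15),
    "16-18": (16, 18),
    "19-65": (19, 65),
    "66+": (66, 200),
}


@dataclass(frozen=True)
class LognormalParams:
    """Log-scale location/scale of a lognormal distribution."""

    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if self.sdlog < 0:
            raise ValueError("sdlog must be nonnegative")

    def arithmetic_moments(self) -> tuple[float, float]:
        mean = float(np.exp(self.meanlog + 0.5 * self.sdlog**2))
        sd = float(mean * np.sqrt(np.expm1(self.sdlog**2)))
        return mean, sd


@dataclass(frozen=True)
class DemographicStratum:
    age: int
    sex: str
    population_count: int
    bw_mean: float
    bw_sd: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.population_count < 0 or self.bw_mean <= 0 or self.bw_sd < 0:
            raise ValueError("invalid stratum")


@dataclass(frozen=True)
class IntakeSpec:
    category: str
    scenario: str
    intake_mean: float
    intake_sd: float
    group_key: str = "all"

    def __post_init__(self) -> None:
        if self.scenario not in ("LB", "UB"):
            raise ValueError("scenario must be 'LB' or 'UB'")
        if self.intake_mean < 0 or self.intake_sd < 0:
            raise ValueError("intake moments must be nonnegative")


def lognormal_params_from_moments(mean: float, sd: float) -> LognormalParams:
    """Exact moment-matching map from arithmetic (mean, SD) to (meanlog, sdlog).

    meanlog = ln(mean^2 / sqrt(sd^2 + mean^2)),  sdlog = sqrt(ln(1 + sd^2/mean^2))
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if sd == 0:
        return LognormalParams(float(np.log(mean)), 0.0)
    ratio2 = (sd / mean) ** 2
    return LognormalParams(
        meanlog=float(np.log(mean / np.sqrt(1.0 + ratio2))),
        sdlog=float(np.sqrt(np.log1p(ratio2))),
    )


def sample_truncated_normal(
    mean: float,
    sd: float,
    lower: float,
    upper: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` values from Normal(mean, sd) truncated to [lower, upper]."""
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if sd == 0:
        return np.full(n, float(np.clip(mean, lower, upper)))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def allocate_population(
    strata: list[DemographicStratum],
    n_total: int,
    min_per_stratum: int = 10,
) -> np.ndarray:
    """Allocate simulated individuals to strata.

    Largest-remainder rounding of counts proportional to the registry
    population, then every populated stratum is raised to ``min_per_stratum``
    with compensating reductions taken from the currently largest strata.
    Ties break deterministically by stratum order.
    """
    weights = np.array([s.population_count for s in strata], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no population in any stratum")
    populated = weights > 0
    if n_total < min_per_stratum * populated.sum():
        raise ValueError("n_total too small to honour min_per_stratum")

    quota = n_total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_total - counts.sum()
    # stable: largest remainder first, earlier stratum wins ties
    order = np.lexsort((np.arange(len(strata)), -remainder))
    counts[order[:short]] += 1

    need = populated & (counts < min_per_stratum)
    while need.any():
        deficit = int((min_per_stratum - counts[need]).sum())
        counts[need] = min_per_stratum
        for _ in range(deficit):
            donor_ok = populated & (counts > min_per_stratum)
            donor = int(np.argmax(np.where(donor_ok, counts, -1)))
            counts[donor] -= 1
        need = populated & (counts < min_per_stratum)
    assert counts.sum() == n_total
    return counts


def aggregate_exposure(
    intakes: np.ndarray, residues: np.ndarray, bodyweight: float | np.ndarray
) -> np.ndarray | float:
    """Aggregate dose in mg/kg/day; intakes g/day, residues ppm (mg/kg food)."""
    intakes = np.asarray(intakes, dtype=float)
    residues = np.asarray(residues, dtype=float)
    if np.any(intakes < 0) or np.any(residues < 0):
        raise ValueError("intakes and residues must be nonnegative")
    if np.any(np.asarray(bodyweight) <= 0):
        raise ValueError("bodyweight must be positive")
    return np.sum(intakes * residues, axis=-1) / (bodyweight * 1000.0)


def run_exposure_scenario(
    strata: list[DemographicStratum],
    residue_params: dict[str, LognormalParams],
    intake_specs: list[IntakeSpec],
    scenario: str,
    seed: int,
    n_total: int = 200_000,
    min_per_stratum: int = 10,
    bw_trunc_sds: float = 4.0,
    intake_trunc_sds: float = 6.0,
) -> pd.DataFrame:
    """Simulate one scenario and return the per-individual exposure table.

    Body weight is truncated to [max(0.5, mean - 4 sd), mean + 4 sd] kg and
    intakes to [0, mean + 6 sd] g/day; residues are drawn independently per
    individual and category from the posterior lognormals.
    """
    specs = {s.category: s for s in intake_specs if s.scenario == scenario}
    missing = set(residue_params) - set(specs)
    if missing:
        raise ValueError(f"no {scenario} intake spec for categories: {sorted(missing)}")
    categories = sorted(residue_params)

    counts = allocate_population(strata, n_total, min_per_stratum)
    rng = np.random.default_rng(seed)

    ages = np.repeat([s.age for s in strata], counts)
    sexes = np.repeat([s.sex for s in strata], counts)
    bw = np.empty(n_total)
    pos = 0
    for s, c in zip(strata, counts):
        lo = max(0.5, s.bw_mean - bw_trunc_sds * s.bw_sd)
        hi = s.bw_mean + bw_trunc_sds * s.bw_sd
        if s.bw_sd == 0:
            bw[pos : pos + c] = s.bw_mean
        else:
            bw[pos : pos + c] = sample_truncated_normal(s.bw_mean, s.bw_sd, lo, hi, c, rng)
        pos += c

    intake_mat = np.empty((n_total, len(categories)))
    residue_mat = np.empty((n_total, len(categories)))
    for k, cat in enumerate(categories):
        sp = specs[cat]
        hi = sp.intake_mean + intake_trunc_sds * sp.intake_sd
        if sp.intake_sd == 0 or hi == 0:
            intake_mat[:, k] = sp.intake_mean
        else:
            intake_mat[:, k] = sample_truncated_normal(sp.intake_mean, sp.intake_sd, 0.0, hi, n_total, rng)
        p = residue_params[cat]
        if p.sdlog == 0:
            residue_mat[:, k] = np.exp(p.meanlog)
        else:
            residue_mat[:, k] = rng.lognormal(p.meanlog, p.sdlog, size=n_total)

    exposure = aggregate_exposure(intake_mat, residue_mat, bw)
    df = pd.DataFrame(
        {"id": np.arange(n_total), "age": ages, "sex": sexes, "bodyweight": bw, "exposure": exposure}
    )
    contrib = intake_mat * residue_mat / (bw[:, None] * 1000.0)
    for k, cat in enumerate(categories):
        df[f"dose_{cat}"] = contrib[:, k]
    df.attrs["scenario"] = scenario
    return df


def summarize_exposure(table: pd.DataFrame) -> pd.DataFrame:
    """Exposure summaries by age group and by sex (mean, SD, quantiles)."""
    rows = []

    def _stats(label: str, sub: pd.Series) -> dict:
        q = sub.quantile([0.5, 0.95, 0.99])
        return {
            "group": label,
            "n": int(sub.size),
            "mean": sub.mean(),
            "sd": sub.std(),
            "p50": q[0.5],
            "p95": q[0.95],
            "p99": q[0.99],
        }

    for label, (lo, hi) in AGE_GROUPS.items():
        sub = table.loc[(table["age"] >= lo) & (table["age"] <= hi), "exposure"]
        if sub.size:
            rows.append(_stats(label, sub))
    for sex in ("male", "female"):
        sub = table.loc[table["sex"] == sex, "exposure"]
        if sub.size:
            rows.append(_stats(sex, sub))
    return pd.DataFrame(rows)


def load_demographics(path: str | Path) -> list[DemographicStratum]:
    df = pd.read_csv(path)
    return [
        DemographicStratum(
            age=int(r["age"]),
            sex=str(r["sex"]),
            population_count=int(r["count"]),
            bw_mean=float(r["bw_mean"]),
            bw_sd=float(r["bw_sd"]),
        )
        for r in df.to_dict("records")
    ]


def load_intakes(path: str | Path) -> list[IntakeSpec]:
    df = pd.read_csv(path)
    return [
        IntakeSpec(
            category=str(r["category"]),
            scenario=str(r["scenario"]),
            intake_mean=float(r["mean"]),
            intake_sd=float(r["sd"]),
            group_key=str(r.get("group_key", "all")),
        )
        for r in df.to_dict("records")
    ]
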