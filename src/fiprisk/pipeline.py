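"""End-to-end orchestration: reconstruct -> expose -> bmd -> rfd -> risk.

Each stage consumes only files written by earlier stages, so any stage can be
re-run in isolation.  Per-stage seeds are derived deterministically from the
master seed and the stage name; a manifest records configuration, seeds and
convergence flags so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import doseresponse, exposure, prfd, residues, risk
from .mcmc import McmcSettings

__all__ = ["RunConfig", "run_full_assessment", "summarize_results", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Paths and settings for a full assessment run."""

    residues_csv: str
    demographics_csv: str
    intakes_csv: str
    dose_response_csv: str
    output_dir: str
    master_seed: int = 1
    scenarios: tuple[str, ...] = ("LB", "UB")
    n_individuals: int = 200_000
    min_per_stratum: int = 10
    residue_chains: int = 4
    residue_iterations: int = 25_000
    bmd_chains: int = 3
    bmd_iterations: int = 50_000
    bmd_seed: int = 76_316
    weight_scheme: str = "bic"
    bw_animal: float = 0.35
    noael: float = 0.019
    safety_factor: float = 100.0
    fix_rl: float | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        if "scenarios" in known:
            known["scenarios"] = tuple(known["scenarios"])
        return cls(**known)

    def validate(self) -> None:
        for name in ("residues_csv", "demographics_csv", "intakes_csv", "dose_response_csv"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config input '{name}' not found: {p}")


def _stage_reconstruct(config: RunConfig, outdir: Path, manifest: dict) -> dict:
    datasets = residues.load_residue_datasets(config.residues_csv)
    seed = stage_seed(config.master_seed, "reconstruct")
    fits = {}
    for i, (cat, ds) in enumerate(sorted(datasets.items())):
        settings = McmcSettings(
            n_chains=config.residue_chains,
            n_iter=config.residue_iterations,
            seed=seed + i,
        )
        fits[cat] = residues.fit_censored_lognormal(ds, mcmc=settings, fix_rl=config.fix_rl)
    path = outdir / "residue_fits.json"
    residues.fits_to_json(fits, path)
    manifest["stages"]["reconstruct"] = {
        "seed": seed,
        "converged": {c: f.converged for c, f in fits.items()},
        "output": str(path),
    }
    return fits


def _stage_expose(config: RunConfig, outdir: Path, manifest: dict) -> dict[str, pd.DataFrame]:
    with open(outdir / "residue_fits.json") as fh:
        fits = json.load(fh)
    bad = sorted(c for c, f in fits.items() if not f["converged"])
    if bad:
        raise RuntimeError(
            f"residue fits did not converge for {bad}; rerun the reconstruct "
            "stage with more iterations before simulating exposure"
        )
    params = {
        cat: exposure.lognormal_params_from_moments(f["mean_est"], f["std_est"])
        for cat, f in fits.items()
    }
    strata = exposure.load_demographics(config.demographics_csv)
    intake_specs = exposure.load_intakes(config.intakes_csv)
    tables = {}
    info = {}
    for scenario in config.scenarios:
        seed = stage_seed(config.master_seed, f"expose-{scenario}")
        table = exposure.run_exposure_scenario(
            strata,
            params,
            intake_specs,
            scenario,
            seed=seed,
            n_total=config.n_individuals,
            min_per_stratum=config.min_per_stratum,
        )
        path = outdir / f"exposure_{scenario}.csv"
        table.to_csv(path, index=False)
        summary = exposure.summarize_exposure(table)
        summary.to_csv(outdir / f"exposure_summary_{scenario}.csv", index=False)
        tables[scenario] = table
        info[scenario] = {"seed": seed, "mean": float(table["exposure"].mean()), "output": str(path)}
    manifest["stages"]["expose"] = info
    return tables


def _stage_bmd(config: RunConfig, outdir: Path, manifest: dict) -> doseresponse.BmdPosterior:
    data = doseresponse.load_dose_response(config.dose_response_csv)
    settings = McmcSettings(
        n_chains=config.bmd_chains, n_iter=config.bmd_iterations, seed=config.bmd_seed
    )
    fits = doseresponse.fit_all_models(data, settings)
    weights = doseresponse.compute_model_weights(fits, scheme=config.weight_scheme)
    avg = doseresponse.model_average_bmd(
        fits, weights, seed=stage_seed(config.master_seed, "bmd-average")
    )
    out = {
        "weights": weights,
        "per_model": {
            n: {"bmd_median": f.bmd_median, "converged": f.converged, "rhat_max": float(f.rhat.max())}
            for n, f in fits.items()
        },
        "averaged_percentiles": avg.percentile_table(),
    }
    (outdir / "bmd.json").write_text(json.dumps(out, indent=2))
    pd.DataFrame({"bmd": avg.averaged_draws}).to_csv(outdir / "bmd_draws.csv", index=False)
    manifest["stages"]["bmd"] = {
        "seed": config.bmd_seed,
        "converged": {n: f.converged for n, f in fits.items()},
        "output": str(outdir / "bmd.json"),
    }
    return avg


def _stage_rfd(config: RunConfig, outdir: Path, manifest: dict) -> prfd.HdmiResult:
    draws = pd.read_csv(outdir / "bmd_draws.csv")["bmd"].to_numpy()
    seed = stage_seed(config.master_seed, "rfd")
    inter = prfd.InterspeciesParams(bw_animal=config.bw_animal)
    result = prfd.derive_hdmi(draws, inter=inter, seed=seed)
    (outdir / "prfd.json").write_text(json.dumps(result.to_dict(), indent=2))
    manifest["stages"]["rfd"] = {"seed": seed, "prfd": result.prfd, "output": str(outdir / "prfd.json")}
    return result


def _stage_risk(config: RunConfig, outdir: Path, manifest: dict) -> list[risk.RiskSummary]:
    with open(outdir / "prfd.json") as fh:
        prfd_value = json.load(fh)["prfd"]
    adi = risk.derive_adi(config.noael, config.safety_factor)
    summaries = []
    for scenario in config.scenarios:
        table = pd.read_csv(outdir / f"exposure_{scenario}.csv")
        for name, ref in (("ADI", adi), ("pRfD", prfd_value)):
            summaries.append(risk.exceedance_summary(table, ref, name, scenario))
    out = [s.to_dict() for s in summaries]
    (outdir / "risk.json").write_text(json.dumps(out, indent=2))
    manifest["stages"]["risk"] = {"adi": adi, "prfd": prfd_value, "output": str(outdir / "risk.json")}
    return summaries


def run_full_assessment(config: RunConfig) -> dict:
    """Execute all five stages in order; returns the run manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "config": {k: v for k, v in vars(config).items() if not isinstance(v, dict)},
        "stages": {},
    }
    for stage, fn in [
        ("reconstruct", _stage_reconstruct),
        ("expose", _stage_expose),
        ("bmd", _stage_bmd),
        ("rfd", _stage_rfd),
        ("risk", _stage_risk),
    ]:
        try:
            fn(config, outdir, manifest)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def summarize_results(output_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Collect the report tables of a completed run.

    Returns exposure summaries per scenario, the reference-dose percentile
    table (columns ordered BMD / HD50 / HDMI) and the risk summaries.
    """
    outdir = Path(output_dir)
    if not (outdir / "manifest.json").exists():
        raise FileNotFoundError("no manifest.json: run is incomplete")
    tables: dict[str, pd.DataFrame] = {}
    for scenario_file in sorted(outdir.glob("exposure_summary_*.csv")):
        tables[scenario_file.stem] = pd.read_csv(scenario_file)
    with open(outdir / "prfd.json") as fh:
        p = json.load(fh)
    tables["reference_dose_percentiles"] = pd.DataFrame(p["percentiles"])[["BMD", "HD50", "HDMI"]]
    with open(outdir / "risk.json") as fh:
        risk_data = json.load(fh)
    tables["risk"] = pd.DataFrame(
        [
            {k: v for k, v in entry.items() if k != "by_group"}
            for entry in risk_data
        ]
    )
    return tables
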