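"""Hazard-quotient risk characterization.

HQ = aggregate exposure / reference dose; the reference dose is either the
deterministic ADI (NOAEL / safety factor) or the probabilistic RfD (the
lower 5th percentile of the HDMI distribution).  HQ > 1 flags an individual
whose simulated chronic dose exceeds the reference; HQ exactly 1 is counted
as a non-exceedance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import AGE_GROUPS

__all__ = [
    "ReferenceValues",
    "RiskSummary",
    "derive_adi",
    "hazard_quotient",
    "exceedance_summary",
]


def derive_adi(noael: float = 0.019, safety_factor: float = 100.0) -> float:
    """Deterministic acceptable daily intake: NOAEL / safety factor."""
    if noael <= 0 or safety_factor <= 0:
        raise ValueError("NOAEL and safety factor must be positive")
    return noael / safety_factor


@dataclass(frozen=True)
class ReferenceValues:
    """Deterministic and probabilistic reference doses (mg/kg/day)."""

    noael: float = 0.019
    safety_factor: float = 100.0
    prfd: float | None = None

    @property
    def adi(self) -> float:
        return derive_adi(self.noael, self.safety_factor)


def hazard_quotient(exposure: np.ndarray | float, reference: float) -> np.ndarray | float:
    """Exposure divided by the reference dose (both mg/kg/day)."""
    if reference <= 0:
        raise ValueError("reference dose must be positive")
    exposure = np.asarray(exposure, dtype=float)
    if np.any(exposure < 0):
        raise ValueError("exposure must be nonnegative")
    out = exposure / reference
    return float(out) if out.ndim == 0 else out


@dataclass
class RiskSummary:
    """Exceedance counts/fractions of HQ > 1, overall and per group."""

    reference_name: str
    reference_value: float
    scenario: str
    exceedance_count: int
    exceedance_fraction: float
    by_group: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_name,
            "reference_value": self.reference_value,
            "scenario": self.scenario,
            "exceedance_count": self.exceedance_count,
            "exceedance_fraction": self.exceedance_fraction,
            "by_group": self.by_group.to_dict(orient="records"),
        }


def exceedance_summary(
    table: pd.DataFrame,
    reference: float,
    reference_name: str = "ADI",
    scenario: str | None = None,
) -> RiskSummary:
    """Summarize HQ > 1 exceedances by age group and sex.

    ``table`` is a per-individual exposure table with columns
    (age, sex, exposure); HQ exactly 1 does not count as an exceedance.
    """
    hq = hazard_quotient(table["exposure"].to_numpy(), reference)
    exceed = hq > 1.0
    rows = []
    for label, (lo, hi) in AGE_GROUPS.items():
        if label == "all":
            continue
        mask = (table["age"] >= lo) & (table["age"] <= hi)
        if mask.any():
            rows.append(
                {
                    "group": label,
                    "n": int(mask.sum()),
                    "exceedances": int(exceed[mask].sum()),
                    "fraction": float(exceed[mask].mean()),
                    "max_hq": float(hq[mask].max()),
                }
            )
    for sex in ("male", "female"):
        mask = (table["sex"] == sex).to_numpy()
        if mask.any():
            rows.append(
                {
                    "group": sex,
                    "n": int(mask.sum()),
                    "exceedances": int(exceed[mask].sum()),
                    "fraction": float(exceed[mask].mean()),
                    "max_hq": float(hq[mask].max()),
                }
            )
    return RiskSummary(
        reference_name=reference_name,
        reference_value=reference,
        scenario=scenario or table.attrs.get("scenario", "?"),
        exceedance_count=int(exceed.sum()),
        exceedance_fraction=float(exceed.mean()),
        by_group=pd.DataFrame(rows),
    )
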