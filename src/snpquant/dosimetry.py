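"""Corneal surface dose per zone from the prescribed tumour-base dose.

A Ru-106 beta-emitting plaque sutured over an anterior ocular tumour
delivers a steeply falling dose across the cornea.  Isodose modelling of
the published plaque geometry gives fixed surface-dose fractions of the
prescribed tumour-base dose: 0.44% for the cornea directly adjacent to the
plaque, 0.12% for the central third, and 0.015% for the distal third.  Full
Monte-Carlo plaque physics is out of scope; only these fixed fractions are
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ._round import round_half_away

__all__ = [
    "ZoneFractions",
    "DoseRecord",
    "calculated_doses",
    "treatment_duration_h",
    "load_reference_doses",
]


@dataclass(frozen=True)
class ZoneFractions:
    """Surface-dose fractions of the tumour-base dose, by corneal zone."""

    adjacent: float = 0.0044
    central: float = 0.0012
    distal: float = 0.00015

    def __post_init__(self) -> None:
        if not (1.0 > self.adjacent > self.central > self.distal > 0.0):
            raise ValueError("fractions must satisfy 1 > adjacent > central > distal > 0")


@dataclass(frozen=True)
class DoseRecord:
    """Prescribed tumour-base dose and the derived per-zone surface doses (Gy)."""

    prescribed_gy: float
    adjacent_gy: float
    central_gy: float
    distal_gy: float
    dose_rate_gy_per_h: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "prescribed_gy": self.prescribed_gy,
            "adjacent_gy": self.adjacent_gy,
            "central_gy": self.central_gy,
            "distal_gy": self.distal_gy,
        }


def calculated_doses(
    prescribed_gy: float,
    fractions: ZoneFractions | None = None,
    dose_rate_gy_per_h: float | None = None,
) -> DoseRecord:
    """Per-zone corneal surface doses: prescribed dose times zone fraction.

    Values are reported in Gy rounded to 2 decimals, half away from zero.
    """
    if prescribed_gy <= 0:
        raise ValueError("prescribed dose must be positive")
    f = fractions or ZoneFractions()
    return DoseRecord(
        prescribed_gy=prescribed_gy,
        adjacent_gy=round_half_away(prescribed_gy * f.adjacent, 2),
        central_gy=round_half_away(prescribed_gy * f.central, 2),
        distal_gy=round_half_away(prescribed_gy * f.distal, 2),
        dose_rate_gy_per_h=dose_rate_gy_per_h,
    )


def treatment_duration_h(prescribed_gy: float, dose_rate_gy_per_h: float) -> float:
    """Plaque residence time implied by the prescribed dose and dose rate."""
    if prescribed_gy <= 0 or dose_rate_gy_per_h <= 0:
        raise ValueError("dose and dose rate must be positive")
    return prescribed_gy / dose_rate_gy_per_h


def load_reference_doses() -> pd.DataFrame:
    """Published per-patient dosimetry of the nine-eye reference cohort.

    Columns include the prescribed tumour-base dose, the applicator-zone
    dose rate, and the per-zone calculated doses as printed in the source
    summary (``printed_*`` columns) for cross-checking.
    """
    with resources.files("snpquant.data").joinpath("cohort_doses.csv").open() as fh:
        return pd.read_csv(fh)
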