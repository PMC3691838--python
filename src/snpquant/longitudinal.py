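"""Longitudinal analysis: percent-of-baseline trajectories per corneal zone.

The study design divides the cornea into three zones by distance from an
episcleral brachytherapy plaque — applicator (directly beneath the plaque),
central, and distal — and follows subbasal-nerve morphometry and
Cochet-Bonnet corneal sensation at five visits: before irradiation
(baseline) and at 3 days, 1, 4 and 7 months after.  Degeneration and
regeneration are reported as integer percentages of the zone's baseline
group mean.

Bundled reference data (``load_reference_cohort``, ``load_reference_doses``,
``load_reference_sensation``) are the published group summaries of a
nine-patient Ru-106 plaque brachytherapy case series; the underlying raw
images are not publicly deposited, so these tables serve as worked-example
inputs rather than as reproducible raw data.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_away_int

__all__ = [
    "ZONES",
    "TIMEPOINTS",
    "percent_of_baseline",
    "percent_table",
    "aggregate_replicates",
    "quantile",
    "sensation_percent",
    "classify_sensation",
    "validate_filament_mm",
    "load_reference_cohort",
    "load_reference_sensation",
]

#: Corneal zones by distance from the plaque (closed vocabulary).
ZONES = ("applicator", "central", "distal")

#: Visit schedule in ordinal order; baseline precedes all others.
TIMEPOINTS = ("baseline", "day3", "month1", "month4", "month7")

#: Cochet-Bonnet filament band defining normal corneal sensation (mm).
NORMAL_SENSATION_MM = (50.0, 60.0)


def _tp_order(tp: str) -> int:
    try:
        return TIMEPOINTS.index(tp)
    except ValueError:
        raise ValueError(f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}") from None


def load_reference_cohort() -> pd.DataFrame:
    """Published per-zone group means (value ± sd) of the eight normalised
    morphometric parameters at the five visits, all per 1 mm²
    (average single-fibre length is absolute, in um)."""
    with resources.files("snpquant.data").joinpath("cohort_snp_means.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_sensation() -> pd.DataFrame:
    """Published per-zone Cochet-Bonnet filament lengths (mm, mean ± sd)."""
    with resources.files("snpquant.data").joinpath("cohort_sensation.csv").open() as fh:
        return pd.read_csv(fh)


def percent_of_baseline(series: pd.DataFrame, metric: str, zone: str) -> pd.DataFrame:
    """Percent-of-baseline trajectory of one metric in one zone.

    ``series`` is a long-format table with columns ``zone``, ``timepoint``,
    ``metric``, ``value`` (at most one aggregate value per combination).
    Returns a table of (timepoint, percent) where
    ``percent = 100 * value(t) / value(baseline)`` rounded half away from
    zero to the nearest integer; percentages are computed from group means,
    not averaged over per-subject ratios.
    """
    sel = series[(series["metric"] == metric) & (series["zone"] == zone)]
    if sel.empty:
        raise ValueError(f"no rows for metric {metric!r} in zone {zone!r}")
    dup = sel["timepoint"].duplicated()
    if dup.any():
        raise ValueError(f"multiple values per timepoint for {metric!r}/{zone!r}")
    by_tp = dict(zip(sel["timepoint"], sel["value"]))
    if "baseline" not in by_tp:
        raise ValueError(f"missing baseline for {metric!r} in zone {zone!r}")
    base = float(by_tp["baseline"])
    if base <= 0:
        raise ValueError(f"baseline must be positive, got {base}")
    tps = sorted(by_tp, key=_tp_order)
    rows = [
        {"timepoint": tp, "percent": round_half_away_int(100.0 * float(by_tp[tp]) / base)}
        for tp in tps
    ]
    return pd.DataFrame(rows)


def percent_table(series: pd.DataFrame) -> pd.DataFrame:
    """Percent-of-baseline for every (metric, zone) series present.

    Series without a positive baseline are skipped and reported in the
    ``error`` column of a companion row.
    """
    out = []
    for (metric, zone), _ in series.groupby(["metric", "zone"]):
        try:
            tab = percent_of_baseline(series, metric, zone)
        except ValueError as exc:
            out.append({"metric": metric, "zone": zone, "timepoint": None, "percent": None, "error": str(exc)})
            continue
        for _, row in tab.iterrows():
            out.append(
                {"metric": metric, "zone": zone, "timepoint": row["timepoint"], "percent": row["percent"], "error": None}
            )
    return pd.DataFrame(out)


def aggregate_replicates(values: Iterable[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n - 1 denominator; 0 for n = 1).

    The acquisition protocol takes at least three scans per zone; replicate
    scans and per-patient summaries are aggregated as arithmetic mean ± SD.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one value required")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd


def quantile(values: Iterable[float], q: float = 0.5) -> float:
    """Companion quantile (default: median) of replicate or cohort values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one value required")
    return float(np.quantile(arr, q))


def validate_filament_mm(filament_mm: float) -> float:
    """Check a Cochet-Bonnet reading: 0-60 mm in 5 mm steps."""
    if not 0 <= filament_mm <= 60:
        raise ValueError("filament length must lie in [0, 60] mm")
    if filament_mm % 5 != 0:
        raise ValueError("filament length is reduced in 5 mm steps")
    return float(filament_mm)


def sensation_percent(filament_mm: float, baseline_mm: float) -> int:
    """Corneal sensation as an integer percentage of the baseline reading."""
    if not 0 < baseline_mm <= 60:
        raise ValueError("baseline filament length must lie in (0, 60] mm")
    return round_half_away_int(100.0 * filament_mm / baseline_mm)


def classify_sensation(filament_mm: float) -> str:
    """'normal' for readings within the 50-60 mm band, else 'reduced'."""
    lo, hi = NORMAL_SENSATION_MM
    return "normal" if lo <= filament_mm <= hi else "reduced"
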