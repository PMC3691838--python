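import numpy as np
import pandas as pd
import pytest

from snpquant import (
    TIMEPOINTS,
    ZONES,
    aggregate_replicates,
    classify_sensation,
    load_reference_cohort,
    load_reference_sensation,
    percent_of_baseline,
    sensation_percent,
)
from snpquant.longitudinal import percent_table, quantile, validate_filament_mm

COHORT_DOSES = [278, 293, 550, 520, 527, 387, 1070, 500, 573]


def _series(metric, zone, values):
    return pd.DataFrame(
        [
            {"metric": metric, "zone": zone, "timepoint": tp, "value": v}
            for tp, v in zip(TIMEPOINTS, values)
        ]
    )


def test_nfd_applicator_trajectory():
    s = _series("nfd", "applicator", [15.142, 0.693, 3.896, 4.713, 12.945])
    out = percent_of_baseline(s, "nfd", "applicator")
    assert list(out["percent"]) == [100, 5, 26, 31, 85]


def test_snf_distal_trajectory():
    s = _series("snf", "distal", [162.5, 47.9, 126.6, 175.0, 189.6])
    out = percent_of_baseline(s, "snf", "distal")
    assert list(out["percent"]) == [100, 29, 78, 108, 117]


def test_snf_central_trajectory():
    s = _series("snf", "central", [235.4, 6.3, 51.3, 96.9, 116.7])
    out = percent_of_baseline(s, "snf", "central")
    assert list(out["percent"]) == [100, 3, 22, 41, 50]


def test_constant_series_all_100():
    s = _series("x", "central", [7.0] * 5)
    out = percent_of_baseline(s, "x", "central")
    assert list(out["percent"]) == [100] * 5


def test_scale_invariance():
    vals = [15.142, 0.693, 3.896, 4.713, 12.945]
    a = percent_of_baseline(_series("m", "distal", vals), "m", "distal")
    b = percent_of_baseline(
        _series("m", "distal", [v * 3.7 for v in vals]), "m", "distal"
    )
    assert list(a["percent"]) == list(b["percent"])


def test_missing_baseline_rejected():
    s = _series("m", "central", [1, 2, 3, 4, 5]).iloc[1:]
    with pytest.raises(ValueError, match="baseline"):
        percent_of_baseline(s, "m", "central")


def test_zero_baseline_rejected():
    s = _series("m", "central", [0.0, 2, 3, 4, 5])
    with pytest.raises(ValueError):
        percent_of_baseline(s, "m", "central")


def test_duplicate_timepoint_rejected():
    s = pd.concat([_series("m", "central", [1, 2, 3, 4, 5])] * 2)
    with pytest.raises(ValueError, match="multiple"):
        percent_of_baseline(s, "m", "central")


def test_percent_table_reports_errors_per_series():
    good = _series("m", "central", [1, 2, 3, 4, 5])
    bad = _series("m", "distal", [1, 2, 3, 4, 5]).iloc[1:]
    out = percent_table(pd.concat([good, bad]))
    assert out[out["zone"] == "central"]["error"].isna().all()
    assert out[out["zone"] == "distal"]["error"].notna().all()


def test_cohort_mean_522():
    mean, sd = aggregate_replicates(COHORT_DOSES)
    assert round(mean) == 522
    assert sd == pytest.approx(233.02, abs=0.01)


def test_cohort_median_520():
    assert quantile(COHORT_DOSES, 0.5) == 520


def test_two_identical_values():
    assert aggregate_replicates([5, 5]) == (5.0, 0.0)


def test_single_value_sd_zero():
    assert aggregate_replicates([7.0]) == (7.0, 0.0)


def test_empty_replicates_rejected():
    with pytest.raises(ValueError):
        aggregate_replicates([])


@pytest.mark.parametrize(
    "filament, baseline, expected",
    [(54.0, 58.0, 93), (23.0, 58.0, 40), (60.0, 60.0, 100)],
)
def test_sensation_percent(filament, baseline, expected):
    assert sensation_percent(filament, baseline) == expected


def test_sensation_baseline_validation():
    with pytest.raises(ValueError):
        sensation_percent(50.0, 0.0)


@pytest.mark.parametrize("mm, ok", [(0, True), (55, True), (60, True), (62, False), (-5, False), (53, False)])
def test_validate_filament(mm, ok):
    if ok:
        assert validate_filament_mm(mm) == float(mm)
    else:
        with pytest.raises(ValueError):
            validate_filament_mm(mm)


def test_classify_sensation_band():
    assert classify_sensation(55.0) == "normal"
    assert classify_sensation(50.0) == "normal"
    assert classify_sensation(45.0) == "reduced"


def test_vocabularies():
    assert ZONES == ("applicator", "central", "distal")
    assert TIMEPOINTS[0] == "baseline"
    assert len(TIMEPOINTS) == 5


def test_reference_cohort_shape():
    df = load_reference_cohort()
    assert set(df["zone"]) == set(ZONES)
    assert set(df["timepoint"]) == set(TIMEPOINTS)
    # eight normalised parameters x 3 zones x 5 visits
    assert len(df) == 8 * 3 * 5


def test_reference_sensation_shape():
    df = load_reference_sensation()
    assert len(df) == 3 * 5
    assert df["value"].between(0, 60).all()
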