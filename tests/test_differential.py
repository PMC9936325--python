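import math

import pytest
from hypothesis import given, settings, strategies as st

from sdswitch.differential import (
    DiffClass,
    add_ratio_of_sums,
    classify,
    summarize,
)
from sdswitch.quantify import ExpressionRecord, FeatureType


def _record(rpm_wt, rpm_ko, fid="f", ftype=FeatureType.MIRNA,
            denom_wt=10**6, denom_ko=10**6):
    return ExpressionRecord(
        feature_id=fid, feature_type=ftype,
        raw_wt=rpm_wt * denom_wt / 1e6, raw_ko=rpm_ko * denom_ko / 1e6,
        denom_wt=denom_wt, denom_ko=denom_ko,
        rpm_wt=rpm_wt, rpm_ko=rpm_ko,
    )


@pytest.mark.parametrize(
    "percent,expected",
    [
        (49.99, DiffClass.DOWN),
        (50.0, DiffClass.DOWN),  # the 50% boundary is inclusive for DOWN
        (50.01, DiffClass.UNCHANGED),
        (100.0, DiffClass.UNCHANGED),
        (149.99, DiffClass.UNCHANGED),
        (150.0, DiffClass.UP),  # the 150% boundary is inclusive for UP
        (150.01, DiffClass.UP),
    ],
)
def test_boundary_grid_bit_exact(percent, expected):
    call = classify(_record(100.0, percent))
    assert call.call is expected
    assert call.percent_of_wt == percent


def test_boundaries_exact_across_unequal_denominators():
    # 150% arising from different library sizes must still be exactly UP
    rec = ExpressionRecord(
        feature_id="f", feature_type=FeatureType.SDRNA,
        raw_wt=2, raw_ko=9, denom_wt=1_000_000, denom_ko=3_000_000,
        rpm_wt=2.0, rpm_ko=3.0,
    )
    assert classify(rec).call is DiffClass.UP  # exactly 150.000... %


def test_wt_zero_is_up_with_infinite_percent():
    call = classify(_record(0.0, 60.0))
    assert call.call is DiffClass.UP and math.isinf(call.percent_of_wt)


def test_double_zero_violates_floor_contract():
    with pytest.raises(ValueError, match="floor"):
        classify(_record(0.0, 0.0))


def test_partition_is_total():
    for pct in (0.01, 25, 50, 75, 100, 149, 151, 500):
        assert classify(_record(100.0, float(pct))).call in DiffClass


@settings(max_examples=200, derandomize=True)
@given(
    wt=st.integers(min_value=1, max_value=10**5),
    ko=st.integers(min_value=1, max_value=10**5),
)
def test_label_symmetry_under_library_swap(wt, ko):
    fwd = classify(_record(float(wt), float(ko)))
    rev = classify(_record(float(ko), float(wt)))
    assert rev.percent_of_wt == pytest.approx(1e4 / fwd.percent_of_wt, rel=1e-9)
    # 150% and 50% are not reciprocal thresholds (1e4/150 = 66.7), so the
    # UP<->DOWN exchange is exact only outside the [50, 200] percent zone
    if fwd.percent_of_wt < 50:
        assert (fwd.call, rev.call) == (DiffClass.DOWN, DiffClass.UP)
    elif fwd.percent_of_wt > 200:
        assert (fwd.call, rev.call) == (DiffClass.UP, DiffClass.DOWN)


def test_mean_percent_of_changed_set():
    calls = [classify(_record(100.0, p, fid=f"f{p}")) for p in (5.0, 7.8)]
    summary = summarize(calls)
    cs = summary.per_type[FeatureType.MIRNA]
    assert cs.mean_percent_of_wt_down == pytest.approx(6.4)
    assert cs.n_down == 2 and cs.n_expressed == 2


def test_class_counts():
    percents = [200.0] * 3 + [10.0] * 2 + [100.0] * 5
    calls = [classify(_record(100.0, p, fid=f"f{i}")) for i, p in enumerate(percents)]
    cs = summarize(calls).per_type[FeatureType.MIRNA]
    assert (cs.n_up, cs.n_down, cs.n_unchanged, cs.n_expressed) == (3, 2, 5, 10)


def test_infinite_percent_excluded_from_up_mean_but_counted():
    calls = [
        classify(_record(0.0, 60.0, fid="inf1")),
        classify(_record(100.0, 300.0, fid="finite")),
    ]
    cs = summarize(calls).per_type[FeatureType.MIRNA]
    assert cs.n_up == 2
    assert cs.n_up_infinite == 1
    assert cs.mean_percent_of_wt_up == pytest.approx(300.0)


def test_top10_ranked_by_log2_magnitude_ties_lexicographic():
    # |log2(25/100)| == |log2(400/100)| == 2 -> tie broken by feature id
    calls = [
        classify(_record(100.0, 25.0, fid="b")),
        classify(_record(100.0, 25.0, fid="a")),
        classify(_record(100.0, 6.25, fid="c")),  # |log2| = 4, strongest down
        classify(_record(0.0, 60.0, fid="z-inf")),  # infinite: ranks first among up
        classify(_record(100.0, 400.0, fid="u")),
    ]
    cs = summarize(calls).per_type[FeatureType.MIRNA]
    assert [fid for fid, _ in cs.top_down] == ["c", "a", "b"]
    assert [fid for fid, _ in cs.top_up] == ["z-inf", "u"]


def test_empty_summary_all_zeros():
    summary = summarize([])
    for cs in summary.per_type.values():
        assert cs.n_expressed == cs.n_up == cs.n_down == cs.n_unchanged == 0
        assert math.isnan(cs.mean_percent_of_wt_down)
    assert summary.to_dict()["miRNA"]["mean_percent_of_wt_down"] is None


def test_ratio_of_sums_alternative():
    records = [
        _record(100.0, 10.0, fid="a"),
        _record(300.0, 12.0, fid="b"),
    ]
    calls = [classify(r) for r in records]
    summary = summarize(calls)
    add_ratio_of_sums(summary, calls, records)
    cs = summary.per_type[FeatureType.MIRNA]
    # feature-mean: (10 + 4) / 2 = 7 ; ratio of sums: 100*22/400 = 5.5
    assert cs.mean_percent_of_wt_down == pytest.approx(7.0)
    assert cs.ratio_of_sums_down == pytest.approx(5.5)
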