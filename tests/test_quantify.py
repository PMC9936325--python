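import pytest
from hypothesis import given, settings, strategies as st

from sdswitch.aligner import AlignmentSummary, ReadAlignment
from sdswitch.caller import LocusSide, SdrnaLocus
from sdswitch.quantify import (
    DenominatorMode,
    ExpressionRecord,
    FeatureType,
    apply_floor,
    build_features,
    count_library,
    quantify,
)
from sdswitch.reference import Biotype, MatureArm, PrecursorRecord, ReferenceSet


def _record(rpm_wt, rpm_ko, fid="f"):
    return ExpressionRecord(
        feature_id=fid, feature_type=FeatureType.MIRNA,
        raw_wt=rpm_wt, raw_ko=rpm_ko, denom_wt=10**6, denom_ko=10**6,
        rpm_wt=rpm_wt, rpm_ko=rpm_ko,
    )


def _summary(alignments, total):
    aligned = len({a.read_id for a in alignments})
    return AlignmentSummary(
        total_reads=total, reads_in_length_band=aligned,
        reads_aligned=aligned, alignments=list(alignments),
    )


@pytest.fixture
def mini_setup():
    refset = ReferenceSet(
        [
            PrecursorRecord("miR-x", Biotype.MIRNA_MATURE, "A" * 22),
            PrecursorRecord(
                "hp-1", Biotype.MIRNA_HAIRPIN, "C" * 60,
                mature_annotations=(MatureArm("miR-hp-5p", 0, 22),),
            ),
            PrecursorRecord("SNORD9", Biotype.SNORNA, "G" * 100),
        ]
    )
    loci = [SdrnaLocus("sdRNA-D9", "SNORD9", 40, 62, 50, 22, LocusSide.INTERNAL)]
    return refset, build_features(refset, loci)


def test_definitional_rpm(mini_setup):
    refset, features = mini_setup
    aln = [ReadAlignment(f"r{i}", "miR-x", 0, 22) for i in range(30)]
    records = quantify(features, _summary(aln, 10**6), _summary([], 10**6))
    by_id = {r.feature_id: r for r in records}
    assert by_id["miR-x"].rpm_wt == 30.0
    assert by_id["miR-x"].rpm_ko == 0.0
    assert by_id["sdRNA-D9"].rpm_wt == 0.0  # zero-count feature present


def test_arm_attribution_requires_half_read_overlap(mini_setup):
    refset, features = mini_setup
    # 20-nt reads: one 12/20 inside the arm [0,22), one only 8/20 inside
    inside = ReadAlignment("a", "hp-1", 10, 30)
    outside = ReadAlignment("b", "hp-1", 15, 35)
    counts = count_library(features, _summary([inside, outside], 100))
    assert counts["miR-hp-5p"] == 1


def test_locus_counting_is_anchor_based(mini_setup):
    refset, features = mini_setup
    aln = [
        ReadAlignment("a", "SNORD9", 41, 63),  # within tolerance of anchor 40
        ReadAlignment("b", "SNORD9", 50, 72),  # overlaps locus but wrong 5' end
    ]
    counts = count_library(features, _summary(aln, 100), offset_tolerance=3)
    assert counts["sdRNA-D9"] == 1


def test_fractional_multimapper_splits_weight(mini_setup):
    refset, features = mini_setup
    aln = [
        ReadAlignment("a", "miR-x", 0, 22, multiplicity=2),
        ReadAlignment("a", "SNORD9", 40, 62, multiplicity=2),
    ]
    counts = count_library(features, _summary(aln, 100), fractional=True)
    assert counts["miR-x"] == pytest.approx(0.5)
    assert counts["sdRNA-D9"] == pytest.approx(0.5)


def test_aligned_reads_denominator(mini_setup):
    refset, features = mini_setup
    aln = [ReadAlignment(f"r{i}", "miR-x", 0, 22) for i in range(10)]
    records = quantify(
        features, _summary(aln, 1000), _summary(aln, 1000),
        denominator_mode=DenominatorMode.ALIGNED_READS,
    )
    by_id = {r.feature_id: r for r in records}
    assert by_id["miR-x"].rpm_wt == 10 * 1e6 / 10  # per million *aligned* reads


def test_zero_denominator_is_an_error(mini_setup):
    refset, features = mini_setup
    with pytest.raises(ValueError, match="denominator"):
        quantify(features, _summary([], 0), _summary([], 10))


@pytest.mark.parametrize(
    "rpm_wt,rpm_ko,kept",
    [(29.9, 29.9, False), (0.0, 30.0, True), (30.0, 0.0, True), (30.0, 29.0, True)],
)
def test_expression_floor_either_library(rpm_wt, rpm_ko, kept):
    records = apply_floor([_record(rpm_wt, rpm_ko)], floor=30.0)
    assert bool(records) is kept


def test_floor_monotonicity():
    records = [_record(10 * i, 5 * i, fid=f"f{i}") for i in range(1, 20)]
    previous = None
    for floor in (0, 10, 30, 60, 120, 10**9):
        kept = {r.feature_id for r in apply_floor(records, floor)}
        if previous is not None:
            assert kept <= previous
        previous = kept


@settings(max_examples=50, derandomize=True)
@given(
    n_reads=st.integers(min_value=1, max_value=40),
    total=st.integers(min_value=40, max_value=5000),
    c=st.integers(min_value=2, max_value=20),
)
def test_rpm_scale_invariance(n_reads, total, c):
    # multiplying all counts and the denominator by c leaves every RPM fixed
    refset = ReferenceSet([PrecursorRecord("miR-x", Biotype.MIRNA_MATURE, "A" * 22)])
    features = build_features(refset, [])
    aln = [ReadAlignment(f"r{i}", "miR-x", 0, 22) for i in range(n_reads)]
    aln_scaled = [ReadAlignment(f"r{i}", "miR-x", 0, 22) for i in range(n_reads * c)]
    (base,) = quantify(features, _summary(aln, total), _summary(aln, total))
    (scaled,) = quantify(
        features, _summary(aln_scaled, total * c), _summary(aln_scaled, total * c)
    )
    assert scaled.rpm_wt == pytest.approx(base.rpm_wt, rel=1e-12)
    assert scaled.rpm_ko == pytest.approx(base.rpm_ko, rel=1e-12)


def test_duplicate_feature_ids_rejected(mini_setup):
    refset, _ = mini_setup
    loci = [
        SdrnaLocus("miR-x", "SNORD9", 10, 32, 5, 22, LocusSide.INTERNAL),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        build_features(refset, loci)
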