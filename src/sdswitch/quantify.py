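"""Per-feature read counting, RPM normalization, and the expression floor.

Features are either miRNAs (mature reference records, or annotated arms of
hairpin records) or called sdRNA loci. Counting rules:

* mature miRNA — every alignment to that record;
* hairpin arm — alignments on the hairpin overlapping the arm interval by at
  least half the read length;
* sdRNA locus — alignments whose 5' end lies within the caller's offset
  tolerance of the locus anchor (fragment-species counting, consistent with
  how the locus was called).

RPM is raw count x 10^6 / library denominator. The denominator is the total
number of reads in the library by default ("per million sequenced reads");
``aligned_reads`` is available since the convention is genuinely ambiguous.
The expression floor keeps a feature if it reaches the threshold (30 RPM by
default) in at least one of the two libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .aligner import AlignmentSummary
from .caller import SdrnaLocus
from .reference import Biotype, ReferenceSet

logger = logging.getLogger(__name__)


class FeatureType(Enum):
    MIRNA = "miRNA"
    SDRNA = "sdRNA"


class DenominatorMode(Enum):
    TOTAL_READS = "total_reads"
    ALIGNED_READS = "aligned_reads"


class _Counting(Enum):
    WHOLE = "whole"
    ARM_OVERLAP = "arm_overlap"
    ANCHOR = "anchor"


@dataclass(frozen=True)
class Feature:
    feature_id: str
    feature_type: FeatureType
    precursor_id: str
    start: int | None
    end: int | None
    counting: _Counting


@dataclass
class ExpressionRecord:
    """A feature's raw counts and RPM in the (WT, KO) library pair."""

    feature_id: str
    feature_type: FeatureType
    raw_wt: float
    raw_ko: float
    denom_wt: int
    denom_ko: int
    rpm_wt: float
    rpm_ko: float


def build_features(refset: ReferenceSet, loci: list[SdrnaLocus]) -> list[Feature]:
    """The countable feature set: miRNA matures/arms plus called sdRNA loci."""
    features: list[Feature] = []
    for rec in refset:
        if rec.biotype is Biotype.MIRNA_MATURE:
            features.append(
                Feature(rec.id, FeatureType.MIRNA, rec.id, None, None, _Counting.WHOLE)
            )
        elif rec.biotype is Biotype.MIRNA_HAIRPIN:
            for arm in rec.mature_annotations:
                features.append(
                    Feature(
                        arm.name, FeatureType.MIRNA, rec.id,
                        arm.start, arm.end, _Counting.ARM_OVERLAP,
                    )
                )
    for locus in loci:
        features.append(
            Feature(
                locus.sdrna_id, FeatureType.SDRNA, locus.host_id,
                locus.start, locus.end, _Counting.ANCHOR,
            )
        )
    ids = [f.feature_id for f in features]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids: {dup}")
    return features


def count_library(
    features: list[Feature],
    alignments: AlignmentSummary,
    fractional: bool = False,
    offset_tolerance: int = 3,
) -> dict[str, float]:
    """Raw count per feature for one library.

    A multi-mapping read contributes to every feature it matches; with
    ``fractional`` each placement contributes 1/multiplicity instead.
    """
    by_precursor: dict[str, list[Feature]] = {}
    for f in features:
        by_precursor.setdefault(f.precursor_id, []).append(f)
    counts = {f.feature_id: 0.0 for f in features}
    for a in alignments.alignments:
        w = 1.0 / a.multiplicity if fractional else 1.0
        n = a.end - a.start
        for f in by_precursor.get(a.precursor_id, ()):
            if f.counting is _Counting.WHOLE:
                counts[f.feature_id] += w
            elif f.counting is _Counting.ARM_OVERLAP:
                overlap = min(a.end, f.end) - max(a.start, f.start)
                if 2 * overlap >= n:
                    counts[f.feature_id] += w
            else:  # ANCHOR
                if abs(a.start - f.start) <= offset_tolerance:
                    counts[f.feature_id] += w
    return counts


def quantify(
    features: list[Feature],
    alignments_wt: AlignmentSummary,
    alignments_ko: AlignmentSummary,
    denominator_mode: DenominatorMode = DenominatorMode.TOTAL_READS,
    fractional: bool = False,
    offset_tolerance: int = 3,
) -> list[ExpressionRecord]:
    """One :class:`ExpressionRecord` per feature over the WT/KO pair."""
    denoms = []
    for summary in (alignments_wt, alignments_ko):
        d = (
            summary.total_reads
            if denominator_mode is DenominatorMode.TOTAL_READS
            else summary.reads_aligned
        )
        if d <= 0:
            raise ValueError(
                f"library denominator is zero ({denominator_mode.value}); "
                "cannot compute RPM"
            )
        denoms.append(d)
    counts_wt = count_library(features, alignments_wt, fractional, offset_tolerance)
    counts_ko = count_library(features, alignments_ko, fractional, offset_tolerance)
    return [
        ExpressionRecord(
            feature_id=f.feature_id,
            feature_type=f.feature_type,
            raw_wt=counts_wt[f.feature_id],
            raw_ko=counts_ko[f.feature_id],
            denom_wt=denoms[0],
            denom_ko=denoms[1],
            rpm_wt=counts_wt[f.feature_id] * 1e6 / denoms[0],
            rpm_ko=counts_ko[f.feature_id] * 1e6 / denoms[1],
        )
        for f in features
    ]


def apply_floor(
    records: list[ExpressionRecord], floor: float = 30.0
) -> list[ExpressionRecord]:
    """Keep features expressed at >= ``floor`` RPM in at least one library."""
    kept = [r for r in records if max(r.rpm_wt, r.rpm_ko) >= floor]
    for ftype in FeatureType:
        n_in = sum(1 for r in records if r.feature_type is ftype)
        n_out = sum(1 for r in kept if r.feature_type is ftype)
        logger.info(
            "%s: kept %d/%d features at the %.3g RPM floor",
            ftype.value, n_out, n_in, floor,
        )
    return kept


def write_expression_tsv(
    records: list[ExpressionRecord], kept_ids: set[str], path
) -> None:
    with open(path, "w") as out:
        out.write("feature_id\ttype\traw_WT\traw_KO\trpm_WT\trpm_KO\tkept\n")
        for r in records:
            out.write(
                f"{r.feature_id}\t{r.feature_type.value}\t{r.raw_wt:g}\t"
                f"{r.raw_ko:g}\t{r.rpm_wt:.6g}\t{r.rpm_ko:.6g}\t"
                f"{int(r.feature_id in kept_ids)}\n"
            )
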