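"""Three-way differential classification of KO vs WT expression.

Each expressed feature is scored as percent-of-WT, 100 x RPM(KO) / RPM(WT),
and classified UP (>= 150%), DOWN (<= 50%) or UNCHANGED (strictly between).
Because the thresholds are inclusive, the comparison is carried out on exact
rationals built from raw counts and library denominators (RPM scale factors
cancel), so a feature sitting exactly at 150% or 50% is classified without
any float-rounding ambiguity.

A feature silent in WT but expressed in KO has an undefined ratio; it is
reported as UP with an infinite percent code. With a single library per
condition no replicate variance exists, so no hypothesis test is run:
"significantly changed" means the threshold rule and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

from .quantify import ExpressionRecord, FeatureType


class DiffClass(Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


@dataclass
class DifferentialCall:
    feature_id: str
    feature_type: FeatureType
    percent_of_wt: float  # math.inf when rpm_WT == 0
    call: DiffClass


@dataclass
class ClassSummary:
    """Per-feature-type class counts and changed-set means."""

    n_expressed: int = 0
    n_up: int = 0
    n_down: int = 0
    n_unchanged: int = 0
    mean_percent_of_wt_down: float = math.nan
    mean_percent_of_wt_up: float = math.nan  # finite percents only
    n_up_infinite: int = 0  # UP features excluded from the mean (WT = 0)
    #: ratio-of-sums alternatives: 100 x sum(rpm_KO)/sum(rpm_WT) over the class
    ratio_of_sums_down: float = math.nan
    ratio_of_sums_up: float = math.nan
    top_down: list[tuple[str, float]] = field(default_factory=list)
    top_up: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class SwitchSummary:
    per_type: dict[FeatureType, ClassSummary]

    def to_dict(self) -> dict:
        def clean(x: float) -> float | str | None:
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, float) and math.isinf(x):
                return "inf"
            return x

        return {
            ftype.value: {
                "n_expressed": s.n_expressed,
                "n_up": s.n_up,
                "n_down": s.n_down,
                "n_unchanged": s.n_unchanged,
                "mean_percent_of_wt_down": clean(s.mean_percent_of_wt_down),
                "mean_percent_of_wt_up": clean(s.mean_percent_of_wt_up),
                "n_up_infinite": s.n_up_infinite,
                "ratio_of_sums_down": clean(s.ratio_of_sums_down),
                "ratio_of_sums_up": clean(s.ratio_of_sums_up),
                "top_down": [[f, clean(p)] for f, p in s.top_down],
                "top_up": [[f, clean(p)] for f, p in s.top_up],
            }
            for ftype, s in self.per_type.items()
        }


def _exact_percent(record: ExpressionRecord) -> Fraction | None:
    """percent-of-WT as an exact rational; None when WT expression is zero.

    100 * (raw_KO/denom_KO) / (raw_WT/denom_WT); raw counts may be
    non-integer in fractional counting mode, which Fraction handles exactly
    from the float's binary value.
    """
    if record.raw_wt == 0:
        return None
    return (
        100
        * Fraction(record.raw_ko)
        * record.denom_wt
        / (Fraction(record.raw_wt) * record.denom_ko)
    )


def classify(
    record: ExpressionRecord,
    up_threshold: float = 150.0,
    down_threshold: float = 50.0,
) -> DifferentialCall:
    """Assign UP / DOWN / UNCHANGED on the exact percent-of-WT ratio.

    The record must already have passed the expression floor: a feature at
    zero in both libraries has no defined ratio and is rejected.
    """
    if record.raw_wt == 0 and record.raw_ko == 0:
        raise ValueError(
            f"{record.feature_id}: zero expression in both libraries; "
            "classify() requires floored records"
        )
    percent = _exact_percent(record)
    if percent is None:
        return DifferentialCall(
            record.feature_id, record.feature_type, math.inf, DiffClass.UP
        )
    up = Fraction(up_threshold)
    down = Fraction(down_threshold)
    if percent >= up:
        call = DiffClass.UP
    elif percent <= down:
        call = DiffClass.DOWN
    else:
        call = DiffClass.UNCHANGED
    return DifferentialCall(
        record.feature_id, record.feature_type, float(percent), call
    )


def _log2_magnitude(percent: float) -> float:
    """Ranking key for top lists: |log2 fold change|; infinite percent ranks first."""
    if math.isinf(percent):
        return math.inf
    if percent <= 0:
        return math.inf
    return abs(math.log2(percent / 100.0))


def summarize(calls: list[DifferentialCall], top_n: int = 10) -> SwitchSummary:
    """Class counts, changed-set mean percents, and top-N lists per type.

    The DOWN (resp. UP) mean is the arithmetic mean of per-feature
    percent-of-WT over that class; infinite percents (WT = 0) cannot enter a
    mean and are excluded, with the exclusion count reported. Ratio-of-sums
    (100 x total KO RPM / total WT RPM over the class) is emitted alongside
    as the alternative aggregate. Top lists rank by |log2(percent/100)|
    descending, ties broken by feature id.
    """
    summary = SwitchSummary(per_type={})
    for ftype in FeatureType:
        sub = [c for c in calls if c.feature_type is ftype]
        cs = ClassSummary(n_expressed=len(sub))
        downs = [c for c in sub if c.call is DiffClass.DOWN]
        ups = [c for c in sub if c.call is DiffClass.UP]
        cs.n_down = len(downs)
        cs.n_up = len(ups)
        cs.n_unchanged = sum(1 for c in sub if c.call is DiffClass.UNCHANGED)
        finite_ups = [c.percent_of_wt for c in ups if math.isfinite(c.percent_of_wt)]
        cs.n_up_infinite = len(ups) - len(finite_ups)
        if downs:
            cs.mean_percent_of_wt_down = sum(c.percent_of_wt for c in downs) / len(downs)
        if finite_ups:
            cs.mean_percent_of_wt_up = sum(finite_ups) / len(finite_ups)
        ranked = sorted(
            sub, key=lambda c: (-_log2_magnitude(c.percent_of_wt), c.feature_id)
        )
        cs.top_down = [
            (c.feature_id, c.percent_of_wt)
            for c in ranked
            if c.call is DiffClass.DOWN
        ][:top_n]
        cs.top_up = [
            (c.feature_id, c.percent_of_wt)
            for c in ranked
            if c.call is DiffClass.UP
        ][:top_n]
        summary.per_type[ftype] = cs
    return summary


def add_ratio_of_sums(
    summary: SwitchSummary,
    calls: list[DifferentialCall],
    records: list[ExpressionRecord],
) -> None:
    """Fill the ratio-of-sums aggregates from the underlying RPM values."""
    by_id = {r.feature_id: r for r in records}
    for ftype, cs in summary.per_type.items():
        for cls, attr in ((DiffClass.DOWN, "ratio_of_sums_down"), (DiffClass.UP, "ratio_of_sums_up")):
            members = [
                by_id[c.feature_id]
                for c in calls
                if c.feature_type is ftype and c.call is cls and c.feature_id in by_id
            ]
            wt = sum(r.rpm_wt for r in members)
            ko = sum(r.rpm_ko for r in members)
            if wt > 0:
                setattr(cs, attr, 100.0 * ko / wt)
            elif ko > 0:
                setattr(cs, attr, math.inf)


def write_calls_tsv(calls: list[DifferentialCall], path) -> None:
    with open(path, "w") as out:
        out.write("feature_id\ttype\tpercent_of_wt\tcall\n")
        for c in calls:
            pct = "inf" if math.isinf(c.percent_of_wt) else f"{c.percent_of_wt:.6g}"
            out.write(f"{c.feature_id}\t{c.feature_type.value}\t{pct}\t{c.call.value}\n")
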