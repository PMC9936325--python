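"""sdRNA locus calling from snoRNA coverage profiles.

A locus is anchored at a read 5'-end peak: a position whose start-count is a
local maximum and clears a relative floor (``peak_fraction`` of the
profile's maximum start-count). The locus extends from the anchor by the
modal length of the reads starting within ``offset_tolerance`` of it, and
its read count is the number of reads anchored within that tolerance — a
fragment-species count, not pileup depth. The absolute floor (``min_reads``)
applies to that anchored support rather than to the single anchor position:
fragment 5' ends wobble a few nucleotides in real libraries, so a
single-position floor would silently scale with the wobble width.
Overlapping candidates are resolved by keeping the better-supported one.

All five calling knobs are parameters, not constants; the defaults are this
package's concretization of peak-based fragment calling and are validated
against synthetic truth tables rather than any published threshold set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

from .coverage import CoverageProfile
from .reference import MAX_FRAGMENT_LEN, MIN_FRAGMENT_LEN


class LocusSide(Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"
    INTERNAL = "internal"


@dataclass(frozen=True)
class CallerParams:
    min_reads: float = 10.0  # absolute floor on a locus's anchored support
    peak_fraction: float = 0.25  # relative peak floor vs the profile's max start-count
    offset_tolerance: int = 3  # nt; read-to-anchor attribution window
    min_len: int = MIN_FRAGMENT_LEN
    max_len: int = MAX_FRAGMENT_LEN
    edge_margin: int = 5  # nt; 5'/3'-terminal side classification margin


@dataclass
class SdrnaLocus:
    """A called sdRNA fragment interval on its host snoRNA."""

    sdrna_id: str
    host_id: str
    start: int
    end: int
    read_count: float  # integer unless fractional counting is in effect
    modal_length: int
    side: LocusSide


_SNO_NAME = re.compile(r"^SNOR([DA])(\w+)$", re.IGNORECASE)


def name_locus(host_id: str, side: LocusSide | None = None, existing: set[str] | None = None) -> str:
    """Fragment name from its host: SNORD18 -> sdRNA-D18, SNORA31 -> sdRNA-A31.

    The -5p/-3p suffix is attached only when ``side`` is given (i.e. the host
    yielded more than one locus). Arbitrary host names fall back to
    ``sdRNA-<host_id>``. A numeric suffix guarantees uniqueness against
    ``existing``.
    """
    m = _SNO_NAME.match(host_id)
    base = f"sdRNA-{m.group(1).upper()}{m.group(2)}" if m else f"sdRNA-{host_id}"
    if side in (LocusSide.FIVE_PRIME, LocusSide.THREE_PRIME):
        name = f"{base}-{side.value}"
    else:
        name = base
    if existing is not None:
        candidate, k = name, 1
        while candidate in existing:
            k += 1
            candidate = f"{name}.{k}"
        name = candidate
    return name


def _classify_side(start: int, end: int, host_len: int, margin: int) -> LocusSide:
    if start <= margin:
        return LocusSide.FIVE_PRIME
    if host_len - end <= margin:
        return LocusSide.THREE_PRIME
    return LocusSide.INTERNAL


def call_loci(
    profile: CoverageProfile, params: CallerParams = CallerParams()
) -> list[SdrnaLocus]:
    """Call 0..k non-overlapping fragment loci from one profile.

    Returned loci are ranked by read count (descending, ties by start). The
    ``sdrna_id`` fields are provisional (host name only); use
    :func:`name_host_loci` across a host's final locus list for the
    -5p/-3p disambiguation convention.
    """
    sc = profile.start_counts
    if profile.is_empty() or sc.max() <= 0:
        return []
    rel_floor = params.peak_fraction * float(sc.max())
    tol = params.offset_tolerance
    L = profile.length

    # local maxima on start counts; plateaus keep their leftmost position
    peaks = [
        p
        for p in range(L)
        if sc[p] >= rel_floor
        and sc[p] > 0
        and (p == 0 or sc[p] > sc[p - 1])
        and (p == L - 1 or sc[p] >= sc[p + 1])
    ]

    candidates = []
    for p in peaks:
        window = {
            (s, n): w
            for (s, n), w in profile.start_length_counts.items()
            if abs(s - p) <= tol
        }
        count = sum(window.values())
        if count < params.min_reads:
            continue
        # modal read length among anchored reads; ties -> shorter fragment
        by_len: dict[int, float] = {}
        for (s, n), w in window.items():
            by_len[n] = by_len.get(n, 0) + w
        modal = min(
            (n for n in by_len if by_len[n] == max(by_len.values())),
        )
        modal = max(params.min_len, min(params.max_len, modal))
        end = min(p + modal, L)
        candidates.append((float(count), p, end, modal))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    kept: list[tuple[float, int, int, int]] = []
    for cand in candidates:
        _, s, e, _ = cand
        if all(e <= ks or s >= ke for _, ks, ke, _ in kept):
            kept.append(cand)

    loci = [
        SdrnaLocus(
            sdrna_id=profile.precursor_id,
            host_id=profile.precursor_id,
            start=s,
            end=e,
            read_count=float(count) if isinstance(profile.total_reads, float) else int(count),
            modal_length=modal,
            side=_classify_side(s, e, L, params.edge_margin),
        )
        for count, s, e, modal in kept
    ]
    return loci


def name_host_loci(loci: list[SdrnaLocus], existing: set[str] | None = None) -> None:
    """Assign final sdRNA names to all loci of one host, in place.

    A single locus gets the bare host-derived name; exactly two loci are
    disambiguated positionally as -5p (leftmost) and -3p (rightmost); any
    further loci take numeric suffixes via the uniqueness rule.
    """
    existing = existing if existing is not None else set()
    if len(loci) == 1:
        loci[0].sdrna_id = name_locus(loci[0].host_id, existing=existing)
        existing.add(loci[0].sdrna_id)
        return
    by_pos = sorted(loci, key=lambda l: l.start)
    for i, locus in enumerate(by_pos):
        if len(by_pos) == 2:
            side = LocusSide.FIVE_PRIME if i == 0 else LocusSide.THREE_PRIME
            locus.sdrna_id = name_locus(locus.host_id, side=side, existing=existing)
        else:
            locus.sdrna_id = name_locus(locus.host_id, existing=existing)
        existing.add(locus.sdrna_id)


def call_all(
    profiles: dict[str, CoverageProfile],
    params: CallerParams = CallerParams(),
) -> list[SdrnaLocus]:
    """Call and name loci across all profiles; deterministic host order."""
    existing: set[str] = set()
    out: list[SdrnaLocus] = []
    for pid in sorted(profiles):
        loci = call_loci(profiles[pid], params)
        if loci:
            name_host_loci(loci, existing)
            out.extend(loci)
    return out


def write_loci_bed(loci: list[SdrnaLocus], path) -> None:
    """BED6 on precursor coordinates; score = min(1000, read_count)."""
    with open(path, "w") as out:
        for l in loci:
            score = int(min(1000, round(l.read_count)))
            out.write(
                f"{l.host_id}\t{l.start}\t{l.end}\t{l.sdrna_id}\t{score}\t+\n"
            )


def write_loci_tsv(loci: list[SdrnaLocus], path) -> None:
    with open(path, "w") as out:
        out.write("sdrna_id\thost_id\tstart\tend\tread_count\tmodal_length\tside\n")
        for l in loci:
            out.write(
                f"{l.sdrna_id}\t{l.host_id}\t{l.start}\t{l.end}\t"
                f"{l.read_count}\t{l.modal_length}\t{l.side.value}\n"
            )
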