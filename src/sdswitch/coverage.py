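"""Positional coverage profiles over precursors.

For each precursor carrying at least one alignment we record, per position,
how many reads *start* there (5' end counts — the substrate for fragment
locus calling) and how many reads *overlap* it (depth, computed by
difference-array accumulation). In fractional mode each alignment
contributes 1/multiplicity instead of 1; those weights are accumulated as
exact ``fractions.Fraction`` values so conservation identities hold without
float drift, and only exported vectors are floats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .aligner import AlignmentSummary
from .reference import ReferenceSet


class ProfileIntegrityError(ValueError):
    """An alignment interval fell outside its precursor."""


@dataclass
class CoverageProfile:
    """Read-start and depth vectors over one precursor."""

    precursor_id: str
    length: int
    start_counts: np.ndarray  # reads whose 5' end is at position i
    depth: np.ndarray  # reads overlapping position i
    total_reads: float  # sum of alignment weights on this precursor
    #: weight per (start, read length) pair; exact Fractions in fractional mode
    start_length_counts: Counter = field(default_factory=Counter)

    def is_empty(self) -> bool:
        return self.total_reads == 0


def build_profiles(
    alignments: AlignmentSummary,
    refset: ReferenceSet,
    fractional: bool = False,
) -> dict[str, CoverageProfile]:
    """One profile per precursor with >=1 alignment; deterministic.

    Raises :class:`ProfileIntegrityError` if any alignment interval lies
    outside its precursor's bounds (these cannot arise from the aligner, but
    externally supplied alignment tables are checked).
    """
    starts: dict[str, Counter] = {}
    pairs: dict[str, Counter] = {}
    for a in alignments.alignments:
        if a.precursor_id not in refset:
            raise ProfileIntegrityError(f"unknown precursor {a.precursor_id!r}")
        L = refset[a.precursor_id].length
        if not (0 <= a.start < a.end <= L):
            raise ProfileIntegrityError(
                f"alignment [{a.start},{a.end}) outside {a.precursor_id!r} "
                f"of length {L}"
            )
        w = Fraction(1, a.multiplicity) if fractional else 1
        starts.setdefault(a.precursor_id, Counter())[a.start] += w
        pairs.setdefault(a.precursor_id, Counter())[(a.start, a.end - a.start)] += w

    profiles: dict[str, CoverageProfile] = {}
    for pid in sorted(starts):
        L = refset[pid].length
        sc = np.zeros(L, dtype=float)
        diff = np.zeros(L + 1, dtype=float)
        total = Fraction(0)
        for (s, n), w in pairs[pid].items():
            sc[s] += float(w)
            diff[s] += float(w)
            diff[s + n] -= float(w)
            total += w
        depth = np.cumsum(diff[:-1])
        if not fractional:
            sc = sc.astype(np.int64)
            depth = np.rint(depth).astype(np.int64)
        profiles[pid] = CoverageProfile(
            precursor_id=pid,
            length=L,
            start_counts=sc,
            depth=depth,
            total_reads=float(total) if fractional else int(total),
            start_length_counts=pairs[pid],
        )
    return profiles


def write_profile_tsv(profile: CoverageProfile, path) -> None:
    with open(path, "w") as out:
        out.write("position\tstart_count\tdepth\n")
        for i in range(profile.length):
            out.write(f"{i}\t{profile.start_counts[i]}\t{profile.depth[i]}\n")


def write_wiggle(profiles: dict[str, CoverageProfile], path) -> None:
    """Wiggle-like depth track, one fixedStep block per precursor."""
    with open(path, "w") as out:
        for pid in sorted(profiles):
            out.write(f"fixedStep chrom={pid} start=1 step=1\n")
            for v in profiles[pid].depth:
                out.write(f"{v}\n")
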