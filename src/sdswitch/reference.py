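"""Precursor reference handling.

Merges a miRNA FASTA and a snoRNA FASTA into a single validated reference of
small-RNA precursors, and builds an exact-substring index over it.  All
coordinates in this package are precursor-local, 0-based, half-open.

The miRNA input may be either mature sequences (one feature per record) or
hairpin precursors accompanied by a mature-arm annotation table; in the
hairpin case reads are later attributed to arms by overlap.  Sequences are
stored uppercase with U normalized to T, so RNA and DNA dialects of the same
reference are interchangeable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from ._util import open_maybe_gzip

logger = logging.getLogger(__name__)

#: read/fragment length band accepted throughout the pipeline (nt, inclusive)
MIN_FRAGMENT_LEN = 16
MAX_FRAGMENT_LEN = 32

#: sanity band for snoRNA precursor lengths (nt); the canonical class spans
#: roughly 60-300 nt, we warn (not reject) outside a padded 40-350 band
SNORNA_LEN_MIN = 40
SNORNA_LEN_MAX = 350

_SEED_K = 16  # index seed length == minimum accepted fragment length

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Biotype(Enum):
    MIRNA_MATURE = "miRNA_mature"
    MIRNA_HAIRPIN = "miRNA_hairpin"
    SNORNA = "snoRNA"


class SnoClass(Enum):
    CD_BOX = "CD_box"
    HACA_BOX = "HACA_box"
    UNKNOWN = "unknown"


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass(frozen=True)
class MatureArm:
    """A mature-miRNA interval on a hairpin precursor."""

    name: str
    start: int
    end: int


@dataclass
class PrecursorRecord:
    """One reference ncRNA: mature miRNA, miRNA hairpin, or snoRNA."""

    id: str
    biotype: Biotype
    sequence: str
    subclass: SnoClass = SnoClass.UNKNOWN
    mature_annotations: tuple[MatureArm, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"record {self.id!r} has an empty sequence")
        if "U" in self.sequence or self.sequence != self.sequence.upper():
            raise ReferenceError(f"record {self.id!r} not normalized (uppercase, U->T)")
        for arm in self.mature_annotations:
            if not (0 <= arm.start < arm.end <= self.length):
                raise ReferenceError(
                    f"arm {arm.name!r} interval [{arm.start},{arm.end}) outside "
                    f"record {self.id!r} of length {self.length}"
                )
        if self.biotype is Biotype.SNORNA and not (
            SNORNA_LEN_MIN <= self.length <= SNORNA_LEN_MAX
        ):
            logger.warning(
                "snoRNA %s length %d nt outside the %d-%d nt sanity band",
                self.id, self.length, SNORNA_LEN_MIN, SNORNA_LEN_MAX,
            )


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U to T. Other IUPAC letters are kept verbatim."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _classify_snorna(name: str) -> SnoClass:
    up = name.upper()
    if up.startswith("SNORD"):
        return SnoClass.CD_BOX
    if up.startswith("SNORA"):
        return SnoClass.HACA_BOX
    return SnoClass.UNKNOWN


class ReferenceSet:
    """All precursor records plus an exact-substring index.

    The index answers "every sense-strand occurrence of query q" for queries
    in the accepted fragment band. It is seeded on 16-mers: any accepted
    fragment is at least 16 nt, so its leading 16-mer locates every candidate
    placement, which is then verified over the full query. (The same seed
    logic is why a word_size-6 seeded search cannot miss a >=16 nt perfect
    match: every such match contains an exact 6-mer.)
    """

    def __init__(self, records: Iterable[PrecursorRecord] = ()):
        self._records: dict[str, PrecursorRecord] = {}
        self._index: dict[str, list[tuple[str, int]]] | None = None
        for rec in records:
            self.add(rec)

    def add(self, record: PrecursorRecord) -> None:
        record.validate()
        if record.id in self._records:
            raise ReferenceError(f"duplicate record id {record.id!r}")
        self._records[record.id] = record
        self._index = None

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PrecursorRecord]:
        return iter(self._records.values())

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._records

    def __getitem__(self, rec_id: str) -> PrecursorRecord:
        return self._records[rec_id]

    @property
    def records(self) -> dict[str, PrecursorRecord]:
        return self._records

    def counts_by_biotype(self) -> dict[Biotype, int]:
        out: dict[Biotype, int] = {}
        for rec in self:
            out[rec.biotype] = out.get(rec.biotype, 0) + 1
        return out

    # -- index ------------------------------------------------------------

    def build_index(self) -> "ReferenceSet":
        index: dict[str, list[tuple[str, int]]] = {}
        for rec in self:
            seq = rec.sequence
            for pos in range(len(seq) - _SEED_K + 1):
                seed = seq[pos : pos + _SEED_K]
                index.setdefault(seed, []).append((rec.id, pos))
        self._index = index
        return self

    def find(self, query: str) -> list[tuple[str, int]]:
        """All exact sense-strand occurrences of ``query``, as (id, start).

        Returns an empty list for queries outside the 16-32 nt band or
        containing non-ACGT letters (an ambiguous base can never take part
        in a perfect match).
        """
        if self._index is None:
            self.build_index()
        n = len(query)
        if not (MIN_FRAGMENT_LEN <= n <= MAX_FRAGMENT_LEN):
            return []
        if not re.fullmatch(r"[ACGT]+", query):
            return []
        hits = []
        for rec_id, pos in self._index.get(query[:_SEED_K], ()):
            if self._records[rec_id].sequence[pos : pos + n] == query:
                hits.append((rec_id, pos))
        hits.sort()
        return hits

    def contains_substring(self, query: str) -> bool:
        return bool(self.find(query))


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    with open_maybe_gzip(path, "rt") as handle:
        try:
            entries = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
        except ValueError as exc:  # Biopython reports the offending content
            raise ReferenceError(f"malformed FASTA {path}: {exc}") from exc
    if not entries:
        raise ReferenceError(f"FASTA file {path} contains no records")
    return entries


def load_mature_annotations(path: Path) -> dict[str, tuple[MatureArm, ...]]:
    """Parse a mature-arm TSV (hairpin_id, arm_name, start, end; 0-based half-open)."""
    arms: dict[str, list[MatureArm]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "hairpin_id":  # header
                continue
            if len(parts) != 4:
                raise ReferenceError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
                )
            hairpin, arm_name, start, end = parts
            arms.setdefault(hairpin, []).append(
                MatureArm(arm_name, int(start), int(end))
            )
    return {k: tuple(v) for k, v in arms.items()}


def load_reference(
    mirna_fasta: str | Path,
    snorna_fasta: str | Path,
    annotations: str | Path | None = None,
) -> ReferenceSet:
    """Merge miRNA and snoRNA FASTAs into one validated ``ReferenceSet``.

    Biotype is assigned by source file. miRNA records listed in the optional
    mature-arm annotation table become hairpins carrying their arm intervals;
    all other miRNA records are treated as mature sequences. Duplicate ids
    across the two files are rejected.
    """
    arm_table = load_mature_annotations(Path(annotations)) if annotations else {}
    refset = ReferenceSet()
    for rec_id, seq in _read_fasta(Path(mirna_fasta)):
        seq = normalize_sequence(seq)
        if rec_id in arm_table:
            rec = PrecursorRecord(
                rec_id, Biotype.MIRNA_HAIRPIN, seq,
                mature_annotations=arm_table[rec_id],
            )
        else:
            rec = PrecursorRecord(rec_id, Biotype.MIRNA_MATURE, seq)
        refset.add(rec)
    for rec_id, seq in _read_fasta(Path(snorna_fasta)):
        refset.add(
            PrecursorRecord(
                rec_id, Biotype.SNORNA, normalize_sequence(seq),
                subclass=_classify_snorna(rec_id),
            )
        )
    counts = refset.counts_by_biotype()
    logger.info(
        "loaded reference: %s",
        ", ".join(f"{bt.value}={n}" for bt, n in sorted(counts.items(), key=lambda x: x[0].value)),
    )
    return refset


def write_reference_fasta(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in refset:
            out.write(f">{rec.id}\n{rec.sequence}\n")


def write_reference_manifest(refset: ReferenceSet, path: str | Path) -> None:
    """TSV manifest: id, biotype, subclass, length."""
    with open(path, "w") as out:
        out.write("id\tbiotype\tsubclass\tlength\n")
        for rec in refset:
            sub = rec.subclass.value if rec.biotype is Biotype.SNORNA else ""
            out.write(f"{rec.id}\t{rec.biotype.value}\t{sub}\t{rec.length}\n")
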