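"""Exact ungapped placement of small-RNA reads on precursors.

An accepted alignment is a perfect (100% identity), ungapped, full-read match
of length 16-32 nt on the sense strand of a precursor. This is the accepted
set a BLAST+ search with word_size 6, ungapped, 100% identity and the same
length restriction would produce for full-read hits: every perfect match of
at least 16 nt necessarily contains an exact 6-mer seed, so the seeded search
loses nothing relative to an exhaustive scan. An e-value cutoff of 1e-3 is a
no-op at these lengths and identities and is therefore not implemented.

Reads containing N (or any ambiguity code) cannot match anywhere at 100%
identity and are counted but never aligned. Multi-mapping reads are reported
at every placement, with the total placement count recorded as
``multiplicity`` so that downstream counting can optionally fractionalize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO

from ._util import open_maybe_gzip, sniff_format
from .reference import (
    MAX_FRAGMENT_LEN,
    MIN_FRAGMENT_LEN,
    ReferenceSet,
    normalize_sequence,
    reverse_complement,
)

logger = logging.getLogger(__name__)


class Strand(Enum):
    SENSE = "+"
    ANTISENSE = "-"


class ReadParseError(ValueError):
    """Truncated or malformed read file."""


@dataclass(frozen=True)
class ReadAlignment:
    """One perfect ungapped placement of a read on a precursor."""

    read_id: str
    precursor_id: str
    start: int
    end: int  # half-open; end - start == read length
    strand: Strand = Strand.SENSE
    multiplicity: int = 1


@dataclass
class AlignmentSummary:
    """Counters plus the full (deterministic, input-ordered) alignment list."""

    total_reads: int = 0
    reads_in_length_band: int = 0
    reads_aligned: int = 0
    multimapped_reads: int = 0
    alignments: list[ReadAlignment] = field(default_factory=list)


def _placements(seq: str, refset: ReferenceSet, antisense: bool):
    hits: list[tuple[str, int, Strand]] = [
        (rid, pos, Strand.SENSE) for rid, pos in refset.find(seq)
    ]
    if antisense:
        hits += [
            (rid, pos, Strand.ANTISENSE)
            for rid, pos in refset.find(reverse_complement(seq))
        ]
    return hits


def align_read(
    read: str,
    refset: ReferenceSet,
    read_id: str = "read",
    antisense: bool = False,
    partial: bool = False,
) -> list[ReadAlignment]:
    """Every accepted placement of one read; empty if out of band or ambiguous.

    With ``antisense`` enabled, reverse-complement placements are also
    reported (strand '-'), mirroring what a nucleotide BLAST would return;
    by default only sense placements count, since mature small RNAs are
    sense to their precursor.

    With ``partial`` enabled the full-read requirement is relaxed to the
    local-hit dialect: the longest exact substring of the read (within the
    16-32 nt band) that occurs in the reference is placed instead, longest
    windows first. Default is full-read matching: after adapter trimming the
    read *is* the fragment, and local sub-matches would inflate counts.
    """
    seq = normalize_sequence(read)
    hits = _placements(seq, refset, antisense)
    n = len(seq)
    if not hits and partial and len(seq) > MIN_FRAGMENT_LEN:
        for n in range(min(len(seq), MAX_FRAGMENT_LEN), MIN_FRAGMENT_LEN - 1, -1):
            for off in range(len(seq) - n + 1):
                hits += _placements(seq[off : off + n], refset, antisense)
            if hits:
                hits = sorted(set(hits))
                break
    mult = len(hits)
    return [
        ReadAlignment(read_id, rid, pos, pos + n, strand, mult)
        for rid, pos, strand in hits
    ]


def _iter_reads(path: Path):
    fmt = sniff_format(path)
    with open_maybe_gzip(path, "rt") as handle:
        if fmt == "fastq":
            # raw 4-line parsing so a truncated record is reported by index
            idx = 0
            while True:
                header = handle.readline()
                if not header:
                    return
                if not header.strip():
                    continue
                lines = [handle.readline() for _ in range(3)]
                if not header.startswith("@") or any(not l for l in lines):
                    raise ReadParseError(
                        f"{path}: truncated or malformed FASTQ record {idx}"
                    )
                yield header[1:].split()[0], lines[0].strip()
                idx += 1
        else:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq)


def align_library(
    reads: str | Path,
    refset: ReferenceSet,
    antisense: bool = False,
    partial: bool = False,
) -> AlignmentSummary:
    """Align every read of a FASTQ/FASTA library (gzip accepted).

    Streaming and order-preserving: identical input yields bit-identical
    output. Base qualities are ignored (perfect matching makes them moot).
    """
    summary = AlignmentSummary()
    for read_id, seq in _iter_reads(Path(reads)):
        summary.total_reads += 1
        if MIN_FRAGMENT_LEN <= len(seq) <= MAX_FRAGMENT_LEN:
            summary.reads_in_length_band += 1
        hits = align_read(
            seq, refset, read_id=read_id, antisense=antisense, partial=partial
        )
        if hits:
            summary.reads_aligned += 1
            if hits[0].multiplicity > 1:
                summary.multimapped_reads += 1
            summary.alignments.extend(hits)
    logger.info(
        "aligned %d/%d reads (%d in 16-32 nt band, %d multi-mapped)",
        summary.reads_aligned, summary.total_reads,
        summary.reads_in_length_band, summary.multimapped_reads,
    )
    return summary


def write_alignments_tsv(summary: AlignmentSummary, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("read_id\tprecursor_id\tstart\tend\tstrand\tmultiplicity\n")
        for a in summary.alignments:
            out.write(
                f"{a.read_id}\t{a.precursor_id}\t{a.start}\t{a.end}\t"
                f"{a.strand.value}\t{a.multiplicity}\n"
            )


def write_alignments_sam(
    summary: AlignmentSummary, refset: ReferenceSet, path: str | Path
) -> None:
    """SAM with precursors as contigs; flag 16 for antisense, NM:i:0 always."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for rec in refset:
            out.write(f"@SQ\tSN:{rec.id}\tLN:{rec.length}\n")
        for a in summary.alignments:
            n = a.end - a.start
            seq = refset[a.precursor_id].sequence[a.start : a.end]
            if a.strand is Strand.ANTISENSE:
                seq = reverse_complement(seq)
            flag = 0 if a.strand is Strand.SENSE else 16
            out.write(
                f"{a.read_id}\t{flag}\t{a.precursor_id}\t{a.start + 1}\t255\t"
                f"{n}M\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
            )
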