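import gzip

import numpy as np
import pytest

from sdswitch.aligner import (
    ReadParseError,
    Strand,
    align_library,
    align_read,
    write_alignments_sam,
    write_alignments_tsv,
)
from sdswitch.reference import Biotype, PrecursorRecord, ReferenceSet, reverse_complement

from conftest import naive_find


def test_single_placement_coordinates(toy_refset):
    read = toy_refset["SNORD18"].sequence[10:30]
    hits = align_read(read, toy_refset)
    assert [(h.precursor_id, h.start, h.end) for h in hits] == [("SNORD18", 10, 30)]
    assert hits[0].strand is Strand.SENSE and hits[0].multiplicity == 1


@pytest.mark.parametrize(
    "mutate",
    [
        lambda s: s[:15],  # below the 16-nt floor even though present
        lambda s: s[:20] + s[:20],  # 40 nt: above the band
        lambda s: "N" + s[1:20],  # ambiguity cannot match at 100% identity
        lambda s: s[:10] + "A" * 10 if s[10] != "A" else s[:10] + "C" * 10,  # mismatch
    ],
)
def test_rejected_reads_return_empty(toy_refset, mutate):
    read = mutate(toy_refset["SNORD18"].sequence[:32])
    assert align_read(read, toy_refset) == []


def test_rna_read_is_normalized(toy_refset):
    read = toy_refset["mir-b"].sequence.replace("T", "u").lower()
    hits = align_read(read, toy_refset)
    assert [(h.precursor_id, h.start) for h in hits] == [("mir-b", 0)]


def test_multiplicity_counts_all_placements():
    shared = "ACGGATTCCAGGATCCGTTA"
    rs = ReferenceSet(
        [
            PrecursorRecord("x", Biotype.SNORNA, "TTTTTTTTTT" + shared + "GGGGGGGGGG" * 4),
            PrecursorRecord("y", Biotype.SNORNA, "CCCCCCCCCC" + shared + "AAAAAAAAAA" * 4),
        ]
    ).build_index()
    hits = align_read(shared, rs)
    assert len(hits) == 2 and all(h.multiplicity == 2 for h in hits)


def test_antisense_opt_in(toy_refset):
    read = reverse_complement(toy_refset["SNORA31"].sequence[5:25])
    assert align_read(read, toy_refset) == []
    hits = align_read(read, toy_refset, antisense=True)
    assert [(h.precursor_id, h.start, h.end, h.strand) for h in hits] == [
        ("SNORA31", 5, 25, Strand.ANTISENSE)
    ]


def test_partial_mode_places_internal_match(toy_refset):
    window = toy_refset["SNORD18"].sequence[20:44]
    read = "GGGGGGGG" + window + "CCCCCCCC"  # 40 nt, matches only internally
    assert align_read(read, toy_refset) == []
    hits = align_read(read, toy_refset, partial=True)
    assert ("SNORD18", 20, 44) in [(h.precursor_id, h.start, h.end) for h in hits]


def test_oracle_equivalence_random_reads(toy_refset):
    rng = np.random.default_rng(42)
    seqs = [r.sequence for r in toy_refset]
    for _ in range(500):
        if rng.random() < 0.5:
            src = seqs[rng.integers(len(seqs))]
            n = int(rng.integers(14, 36))
            s = int(rng.integers(0, max(1, len(src) - n + 1)))
            read = src[s : s + n]
        else:
            read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 33))))
        got = sorted((h.precursor_id, h.start) for h in align_read(read, toy_refset))
        assert got == naive_find(toy_refset, read)


def _write_fastq(path, reads, gz=False):
    opener = gzip.open if gz else open
    with opener(path, "wt") as out:
        for i, seq in enumerate(reads):
            out.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def test_align_library_counters_and_determinism(toy_refset, tmp_path):
    sno = toy_refset["SNORD18"].sequence
    reads = [sno[0:20], sno[5:27], "A" * 40, "ACGT" * 5, toy_refset["mir-a"].sequence]
    fq = tmp_path / "lib.fastq.gz"
    _write_fastq(fq, reads, gz=True)
    s1 = align_library(fq, toy_refset)
    s2 = align_library(fq, toy_refset)
    assert s1.total_reads == 5
    assert s1.reads_in_length_band == 4  # the 40-mer is out of band
    assert s1.reads_aligned == 3
    assert s1.reads_aligned <= s1.reads_in_length_band <= s1.total_reads
    assert s1.alignments == s2.alignments  # bit-identical rerun


def test_truncated_fastq_reports_record_index(toy_refset, tmp_path):
    fq = tmp_path / "trunc.fastq"
    fq.write_text("@r0\nACGTACGTACGTACGTACGT\n+\nIIIIIIIIIIIIIIIIIIII\n@r1\nACGT\n")
    with pytest.raises(ReadParseError, match="record 1"):
        align_library(fq, toy_refset)


def test_simulated_library_aligned_fraction_matches_background(small_sim):
    refset, result, config = small_sim
    summary = align_library(result.wt_fastq, refset)
    frac = summary.reads_aligned / summary.total_reads
    # all non-background reads align by construction; background never does
    assert frac == pytest.approx(1.0 - config.background_fraction, abs=0.01)


def test_sam_output_parses_with_pysam(toy_refset, tmp_path):
    import pysam

    sno = toy_refset["SNORD18"].sequence
    fq = tmp_path / "lib.fastq"
    _write_fastq(fq, [sno[0:20], sno[30:55]])
    summary = align_library(fq, toy_refset)
    sam = tmp_path / "out.sam"
    write_alignments_sam(summary, toy_refset, sam)
    write_alignments_tsv(summary, tmp_path / "out.tsv")
    with pysam.AlignmentFile(str(sam)) as fh:
        rows = list(fh)
    assert [(r.reference_name, r.reference_start, r.reference_end) for r in rows] == [
        ("SNORD18", 0, 20),
        ("SNORD18", 30, 55),
    ]
    assert all(r.get_tag("NM") == 0 for r in rows)
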