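# sdswitch

Small RNA-seq comparison of microRNA (miRNA) and snoRNA-derived RNA (sdRNA)
expression between a wild-type and a DICER-knockout library.

## The problem

Canonical miRNAs require DICER for maturation, so knocking out DICER
collapses miRNA expression nearly library-wide. snoRNAs — 60–300 nt
nucleolar RNAs — are frequently processed into miRNA-sized fragments
(sdRNAs, ~16–32 nt) by a DICER-*independent* route, and in DICER-deficient
cells those fragments rise as miRNAs fall. Quantifying both classes in one
WT/KO pair of small-RNA libraries makes this expression switch visible as
two mirrored class-level shifts.

`sdswitch` is a reusable pipeline for exactly this comparison, aimed at
people analysing small-RNA fragment data:

1. **Reference** — merge a miRNA FASTA (mature sequences, or hairpins with a
   mature-arm table) and a snoRNA FASTA into one validated precursor set
   with a substring index.
2. **Alignment** — place each read by perfect (100% identity), ungapped,
   full-read matching, restricted to 16–32 nt; multi-mappers are reported at
   every placement with their multiplicity.
3. **Coverage and locus calling** — per-snoRNA read 5′-end and depth
   profiles; sdRNA loci called at 5′-end peaks and extended by the modal
   supported read length, named after their host (`SNORD18` → `sdRNA-D18`).
4. **Quantification** — per-feature RPM
   (`count × 10⁶ / library size`) with an expression floor: a feature is
   kept only if it reaches ≥ 30 RPM in at least one library.
5. **Differential classification** — percent-of-WT
   `100 × RPM_KO / RPM_WT`, classified **UP** (≥ 150 %), **DOWN** (≤ 50 %)
   or **UNCHANGED**, computed on exact rationals so the boundaries are
   bit-exact; class counts, changed-set means and top-10 lists summarize the
   switch.

A seeded synthetic-data module (`sdswitch.simulate`) generates paired WT/KO
libraries with known per-feature ground truth, so every stage is testable
without downloading anything.

## Worked example

```bash
sdswitch simulate --seed 1 --out-dir demo/sim
sdswitch run-all \
    --mirna demo/sim/mirna.fasta --snorna demo/sim/snorna.fasta \
    --annotations demo/sim/mature_arms.tsv \
    --wt demo/sim/wt.fastq.gz --ko demo/sim/ko.fastq.gz \
    --out-dir demo/out
```

prints

```
miRNA: 291 expressed | 258 down, 1 up, 32 unchanged | mean %WT down=6.1 up=170.0
sdRNA: 125 expressed | 0 down, 112 up, 13 unchanged | mean %WT down=nan up=719.7
```

Reading: of 291 miRNAs expressed at ≥ 30 RPM in either library, 258 (88.7 %)
collapse in the knockout to a mean of 6.1 % of their wild-type expression,
while 112 of 125 sdRNA loci (89.6 %) rise, to a mean of 720 % of wild-type —
the two mirrored class-level shifts that constitute the switch.
`demo/out/` contains the full artifact set: alignment-derived expression
table, called loci (BED6 + TSV), per-feature calls, a JSON summary, top-10
lists and a manifest of output hashes.

The same stages are available as a library
(`sdswitch.load_reference`, `sdswitch.align_library`, `sdswitch.call_all`,
`sdswitch.quantify.quantify`, `sdswitch.classify`, `sdswitch.summarize`)
and as individual subcommands (`build-ref`, `align`, `profile`, `call`,
`compare`).

Running against real libraries is the same `run-all` invocation with your
own trimmed FASTQs and reference FASTAs (e.g. miRBase matures plus Ensembl
snoRNAs).

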