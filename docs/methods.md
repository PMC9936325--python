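# Methods

## The comparison

Two adapter-trimmed small-RNA libraries — wild type (WT) and DICER knockout
(KO) — are profiled against a single precursor reference holding all miRNAs
and all snoRNAs of interest. The analysis asks one question per feature:
how does its KO expression compare to WT, on the reads-per-million scale?
Class-level aggregation of the answers (miRNAs versus sdRNA loci) exposes
the switch from DICER-dependent miRNA biogenesis to DICER-independent sdRNA
production.

There is one library per condition, so no replicate variance exists and no
hypothesis test is meaningful; "changed" is a fold-change rule by
construction. All coordinates are precursor-local (0-based, half-open);
genome coordinates are out of scope.

## Alignment model

A read is accepted only as a perfect (100 % identity), ungapped, full-read,
sense-strand match of length 16–32 nt. The index seeds on leading 16-mers
and verifies the full read, which is exhaustively equivalent to a naive
substring scan (property-tested); it is also what a seeded word search with
any word size ≤ 16 would accept for such reads, since a ≥ 16 nt perfect
match always contains an exact seed of any shorter length. Consequences of
this model:

- An E-value cutoff is a no-op for perfect matches of ≥ 16 nt against a
  reference of this size and is not implemented.
- Bases outside `{A,C,G,T}` (after U→T normalization) can never participate
  in a perfect match; reads containing N are counted but never placed.
- Multi-mapping reads are reported at every placement with the placement
  count (`multiplicity`); downstream counting can either credit every
  feature (default, mirrors all-hits reporting) or split each read
  1/multiplicity (`--fractional`, accumulated as exact fractions).
- Two dialect switches exist: `--antisense` also accepts reverse-complement
  placements, and `--allow-partial` relaxes full-read matching to the
  longest exact sub-window ≥ 16 nt. Both are off by default: mature small
  RNAs are sense to their precursor, and after trimming the read *is* the
  fragment, so partial local hits would inflate counts.

miRNA references may be mature sequences (counted whole) or hairpins with a
mature-arm table; a hairpin read is attributed to an arm it overlaps by at
least half the read length.

## sdRNA locus calling

On each snoRNA, the profile of read 5′-end counts is scanned for local
maxima. A peak anchors a locus if (a) its start-count clears
`peak_fraction` of the profile's maximum start-count and (b) the support
anchored within `offset_tolerance` of it reaches `min_reads`. The locus
extends from the anchor by the modal length of its anchored reads (ties to
the shorter length, clamped to 16–32 nt); overlapping candidates resolve to
the better-supported one; surviving loci are named from the host
(`SNORD18 → sdRNA-D18`, `SNORA31 → sdRNA-A31`, `-5p`/`-3p` when one host
yields two loci).

The absolute floor is deliberately applied to anchored support, not to the
single anchor position: fragment 5′ ends wobble a few nucleotides in real
libraries, and a single-position floor would silently tighten as wobble
widens. The relative floor (`peak_fraction`, default 0.25) is a
noise-suppression device: it removes minor 5′-end piles relative to the
host's dominant fragment, and therefore also suppresses genuine sibling
loci expressed below a quarter of the major one — set it to 0 when
sensitivity to minor fragments matters more than shoulder noise. Interval
accuracy is validated against planted synthetic fragments (recovery within
±3 nt); no published threshold set is being reproduced, and all five caller
knobs are configuration, not constants.

Loci are called on the pooled WT+KO alignments so both libraries share one
feature axis; a KO-only fragment is thereby quantifiable (as 0 RPM) in WT.
Locus counts are fragment-species counts — reads whose 5′ end lies within
`offset_tolerance` of the anchor — not pileup depth, so a locus's WT and KO
counts are directly comparable.

## Quantification and classification

RPM = raw count × 10⁶ / library denominator. The denominator is the total
read count of the library (default) or its aligned-read count
(`aligned_reads`); "per million sequenced reads" is the more common
convention, but the choice is exposed because the convention is genuinely
ambiguous. A feature is *expressed* if it reaches ≥ 30 RPM in at least one
library; all others are excluded before classification.

percent-of-WT = 100 × RPM_KO / RPM_WT, computed as an exact rational from
raw counts and denominators (the 10⁶ factors cancel), so the inclusive
boundaries — UP at exactly 150 %, DOWN at exactly 50 % — are decided without
float rounding. A feature with zero WT expression but expressed in KO is UP
with an infinite percent code; the floor guarantees the double-zero case
cannot reach classification.

Class summaries report, per feature type: expressed/up/down/unchanged
counts; the arithmetic mean of per-feature percent-of-WT over the DOWN set
and over the finite UP set (infinite codes cannot enter a mean; their count
is reported alongside); a ratio-of-sums alternative
(100 × Σ RPM_KO / Σ RPM_WT over the class) for comparison; and top-10
lists ranked by |log₂(percent/100)|, infinite percents first, ties by
feature id.

## Synthetic data

The simulator generates the study conditions end to end:

- **Reference.** `n_mirna` = 288 hairpins (5′ arm + 15 nt loop + 3′ arm,
  arms 20–23 nt, both annotated) and `n_snorna` = 103 snoRNAs (uniform
  60–300 nt), each snoRNA hosting one (70 %) or two (30 %) planted fragment
  windows of 16–32 nt. Sequences are resampled until every 16-mer in the
  reference is globally unique, so every truth read has exactly one
  placement (multiplicity 1) and decoys can be screened exactly.
- **WT abundances.** Lognormal weights (σ = 1.0, heavy-tailed as real
  small-RNA libraries are), with one randomly chosen guide arm per hairpin
  carrying the expression and the star arm at 0.1 % of it; sdRNA loci share
  8 % of WT feature mass (`sdrna_wt_mass_fraction`) — sdRNAs are minor
  constituents of a WT small-RNA library.
- **KO effect sizes.** Per-feature KO/WT ratios are lognormal with mean
  0.064 for miRNAs and 6.793 for sdRNAs (σ = 0.5), except a fixed fraction
  per type (10 % of miRNAs, 8 % of sdRNAs) forced to ratio 1.0. KO expected
  abundances are expressed against the *same* library size as WT, with the
  collapsed miRNA mass absorbed by the background component, so a
  configured ratio is exactly the expected RPM ratio the pipeline should
  recover.
- **Reads.** 10⁵ per library by default, multinomially sampled; each truth
  read is the planted window with its ends jittered ±2 nt (clamped to the
  16–32 nt band); 10 % of WT reads are shuffled decoys verified to match
  nowhere. Qualities are constant `I` (alignment is quality-blind). A
  substitution-error knob exists (default 0) to probe count robustness;
  errors can only delete alignments, never create false ones.

Everything is driven by one integer seed and is byte-reproducible,
including the gzip containers (mtime pinned).

What the simulator does *not* emulate — and hence what passing tests do not
establish about real libraries: adapter-trimming artifacts, sequencing
error profiles, non-uniform fragment-end chemistry, paralogous precursors
with shared subsequences (real multi-mapping), other small-RNA classes
(tRFs, rRNA fragments) competing for library mass, and replicate-level
biological variance. The global 16-mer uniqueness in particular makes
synthetic alignment unambiguous in a way real references are not; the
multi-mapping machinery is exercised by dedicated unit tests instead.

## Numerical and design choices

- Exact arithmetic where decisions are made: classification on `Fraction`s;
  fractional counts accumulated as `Fraction`s; depth by integer difference
  arrays.
- Peak plateaus keep their leftmost position; modal-length ties take the
  shorter fragment; overlap resolution prefers higher support, then the
  leftmost start — all deterministic, so calling is idempotent and reruns
  are hash-identical.
- Degenerate inputs: empty alignment sets give empty profile maps; all-zero
  profiles give no loci; an all-filtering floor gives an empty, successful
  summary; a zero library denominator is an error.
- Validation problem sizes: the aligner/oracle equivalence runs 10⁴ random
  reads against a 40-precursor reference; switch recovery runs the default
  288-miRNA / 103-snoRNA reference at 10⁵ reads per library; locus recovery
  plants ~130 fragments across 100 snoRNAs at 5 × 10⁴ reads. These sizes
  make the whole suite run in seconds while leaving every estimate's
  sampling error far smaller than the effects being recovered.
- Recovered class means are judged against the configured targets with the
  simulator's own 95 % confidence interval for a class mean,
  1.96 · s/√n over the recovered changed set.

## Limitations

- The fold-change rule is descriptive, not inferential; with one library
  per condition, "significant" has no statistical content here.
- RPM normalization assumes library size is the right scale; no
  composition-aware size factors are used (with one library per condition
  there is nothing to estimate them from).
- The locus caller assumes fragment 5′ ends are sharply defined (within a
  few nt); diffuse degradation ladders will not produce callable peaks.
- Host names outside the `SNORD`/`SNORA` convention get generic
  `sdRNA-<host>` names.
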