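"""Paired WT / DICER-KO small-RNA library simulation with known ground truth.

The generator emulates the statistical structure of a wild-type vs
DICER-knockout small-RNA sequencing comparison: a reference of miRNA
hairpins (with annotated 20-23 nt mature arms) and snoRNAs (60-300 nt) with
planted sdRNA fragment windows; a WT library dominated by mature-miRNA
reads; and a KO library in which per-miRNA expression collapses to a few
percent of WT while sdRNA fragments rise severalfold. Defaults target a
mean KO/WT ratio of 6.4% for miRNAs and 679.3% for sdRNAs, with a fraction
of each class held unchanged, mirroring the observed switch.

Reads are exact reference substrings (end-jittered within the 16-32 nt
band), so every truth read aligns perfectly; a configurable fraction of
background reads matches nothing. All reference sequences are screened so
that every 16-mer is globally unique, which guarantees multiplicity 1 for
all truth reads. Expected KO feature abundances are expressed relative to
the same library size as WT (the collapsed miRNA mass is absorbed by
background), so configured per-feature KO/WT ratios are exactly the expected
RPM ratios the pipeline should recover.

Abundances and effect sizes are lognormal: strictly positive, heavy-tailed,
the standard choice for expression simulation when only class means are
prescribed.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .caller import LocusSide, name_locus
from .quantify import FeatureType
from .reference import (
    Biotype,
    MatureArm,
    PrecursorRecord,
    ReferenceSet,
)

_BASES = np.array(list("ACGT"))
_K = 16  # uniqueness-screen word size == minimum fragment length


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_mirna: int = 288  # hairpins; one guide arm each carries ~all expression
    n_snorna: int = 103
    reads_per_library: int = 100_000
    mirna_ko_ratio_mean: float = 0.064  # mean KO/WT expression ratio, miRNA
    sdrna_ko_ratio_mean: float = 6.793  # mean KO/WT expression ratio, sdRNA
    ratio_dispersion: float = 0.5  # lognormal sigma of per-feature ratios
    fragment_length_range: tuple[int, int] = (16, 32)
    end_jitter: int = 2  # nt; read ends wander this much around the window
    background_fraction: float = 0.10  # WT reads matching nothing
    unchanged_fraction_mirna: float = 0.10  # forced ratio 1.0
    unchanged_fraction_sdrna: float = 0.08
    sdrna_wt_mass_fraction: float = 0.08  # share of WT feature reads from sdRNAs
    abundance_sigma: float = 1.0  # lognormal sigma of WT feature abundances
    star_arm_fraction: float = 0.001  # star-arm abundance relative to guide arm
    second_fragment_prob: float = 0.3  # chance a snoRNA hosts two sdRNA windows
    error_rate: float = 0.0  # per-read chance of one substitution (robustness knob)

    def validate(self) -> None:
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.mirna_ko_ratio_mean <= 0 or self.sdrna_ko_ratio_mean <= 0:
            raise ValueError("KO/WT ratio means must be positive")
        for name in (
            "background_fraction", "sdrna_wt_mass_fraction",
            "star_arm_fraction", "error_rate",
        ):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in (
            "unchanged_fraction_mirna", "unchanged_fraction_sdrna",
            "second_fragment_prob",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.fragment_length_range
        if not (16 <= lo <= hi <= 32):
            raise ValueError("fragment_length_range must lie within [16, 32]")
        if self.end_jitter < 0:
            raise ValueError("end_jitter must be non-negative")


@dataclass
class TruthFeature:
    """Ground truth for one expressible feature (mature arm or sdRNA window)."""

    feature_id: str
    feature_type: FeatureType
    host_id: str
    start: int
    end: int
    wt_fraction: float = 0.0  # expected share of WT library reads
    ko_fraction: float = 0.0
    ratio: float = 1.0  # expected KO/WT RPM ratio
    true_class: str = "unchanged"
    count_wt: int = 0  # realized sampled counts
    count_ko: int = 0


@dataclass
class TruthTable:
    features: list[TruthFeature] = field(default_factory=list)

    def by_id(self) -> dict[str, TruthFeature]:
        return {f.feature_id: f for f in self.features}

    def of_type(self, ftype: FeatureType) -> list[TruthFeature]:
        return [f for f in self.features if f.feature_type is ftype]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(
                "feature_id\tfeature_type\thost_id\tstart\tend\t"
                "wt_fraction\tko_fraction\tratio\ttrue_class\tcount_wt\tcount_ko\n"
            )
            for f in self.features:
                out.write(
                    f"{f.feature_id}\t{f.feature_type.value}\t{f.host_id}\t"
                    f"{f.start}\t{f.end}\t{f.wt_fraction:.8g}\t{f.ko_fraction:.8g}\t"
                    f"{f.ratio:.8g}\t{f.true_class}\t{f.count_wt}\t{f.count_ko}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _kmers(seq: str) -> set[str]:
    return {seq[i : i + _K] for i in range(len(seq) - _K + 1)}


def _unique_seq(
    rng: np.random.Generator, length: int, seen: set[str], max_tries: int = 50
) -> str:
    """A random sequence whose 16-mers are new and internally distinct."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        kmers = _kmers(seq)
        if len(kmers) == length - _K + 1 and not (kmers & seen):
            seen.update(kmers)
            return seq
    raise SimulationError(
        "could not draw a globally unique sequence; the reference is too "
        "large for the 16-mer space — reduce record counts or lengths"
    )


def simulate_reference(config: SimConfig) -> tuple[ReferenceSet, TruthTable]:
    """Random reference with planted, globally unique fragment windows.

    miRNA hairpins are built as 5p arm + loop + 3p arm with both arms
    annotated (20-23 nt); snoRNA lengths are uniform on [60, 300] with one
    or two planted sdRNA windows each. Every 16-mer in the reference occurs
    exactly once, so any read of >= 16 nt drawn from a planted window has
    exactly one placement.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    refset = ReferenceSet()
    truth = TruthTable()

    for i in range(1, config.n_mirna + 1):
        arm5 = int(rng.integers(20, 24))
        arm3 = int(rng.integers(20, 24))
        loop = 15
        total = arm5 + loop + arm3
        seq = _unique_seq(rng, total, seen)
        hp_id = f"sim-mir-{i:04d}"
        arms = (
            MatureArm(f"sim-miR-{i:04d}-5p", 0, arm5),
            MatureArm(f"sim-miR-{i:04d}-3p", total - arm3, total),
        )
        refset.add(
            PrecursorRecord(
                hp_id, Biotype.MIRNA_HAIRPIN, seq, mature_annotations=arms
            )
        )
        for arm in arms:
            truth.features.append(
                TruthFeature(arm.name, FeatureType.MIRNA, hp_id, arm.start, arm.end)
            )

    frag_lo, frag_hi = config.fragment_length_range
    for i in range(1, config.n_snorna + 1):
        prefix = "SNORD" if rng.random() < 0.7 else "SNORA"
        host_id = f"{prefix}{9000 + i}"  # high numbers: unambiguously synthetic
        length = int(rng.integers(60, 301))
        seq = _unique_seq(rng, length, seen)
        refset.add(PrecursorRecord(host_id, Biotype.SNORNA, seq))

        n_frag = 2 if rng.random() < config.second_fragment_prob else 1
        windows: list[tuple[int, int]] = []
        for _ in range(200):
            if len(windows) == n_frag:
                break
            w = int(rng.integers(frag_lo, frag_hi + 1))
            if length - w <= 0:
                continue
            s = int(rng.integers(0, length - w + 1))
            # keep windows well apart so each anchors its own locus
            if all(s + w + 8 <= ws or s >= we + 8 for ws, we in windows):
                windows.append((s, s + w))
        windows.sort()
        for j, (s, e) in enumerate(windows):
            if len(windows) == 1:
                fid = name_locus(host_id)
            else:
                side = LocusSide.FIVE_PRIME if j == 0 else LocusSide.THREE_PRIME
                fid = name_locus(host_id, side=side)
            truth.features.append(
                TruthFeature(fid, FeatureType.SDRNA, host_id, s, e)
            )

    refset.build_index()
    return refset, truth


def _assign_abundances(truth: TruthTable, config: SimConfig, rng) -> None:
    """Fill wt/ko expected fractions, ratios, and true classes in place."""
    mirna = truth.of_type(FeatureType.MIRNA)
    sdrna = truth.of_type(FeatureType.SDRNA)

    # guide/star structure: per hairpin, one arm carries the expression
    weights_mi = np.empty(len(mirna))
    by_host: dict[str, list[int]] = {}
    for idx, f in enumerate(mirna):
        by_host.setdefault(f.host_id, []).append(idx)
    for idxs in by_host.values():
        guide = idxs[int(rng.integers(0, len(idxs)))]
        w = float(rng.lognormal(0.0, config.abundance_sigma))
        for idx in idxs:
            weights_mi[idx] = w if idx == guide else w * config.star_arm_fraction
    weights_sd = rng.lognormal(0.0, config.abundance_sigma, size=len(sdrna))

    mass_sd = config.sdrna_wt_mass_fraction if sdrna else 0.0
    mass_mi = (1.0 - mass_sd) if mirna else 0.0
    if mirna:
        weights_mi *= mass_mi / weights_mi.sum()
    if sdrna:
        weights_sd *= mass_sd / weights_sd.sum()

    feature_mass = 1.0 - config.background_fraction
    for group, weights, mean, unchanged in (
        (mirna, weights_mi, config.mirna_ko_ratio_mean, config.unchanged_fraction_mirna),
        (sdrna, weights_sd, config.sdrna_ko_ratio_mean, config.unchanged_fraction_sdrna),
    ):
        sigma = config.ratio_dispersion
        mu = math.log(mean) - sigma * sigma / 2.0  # so E[ratio] == mean
        for f, w in zip(group, weights):
            f.wt_fraction = float(w) * feature_mass
            if rng.random() < unchanged:
                f.ratio = 1.0
            else:
                f.ratio = float(rng.lognormal(mu, sigma))
            f.ko_fraction = f.wt_fraction * f.ratio
            if f.ratio >= 1.5:
                f.true_class = "up"
            elif f.ratio <= 0.5:
                f.true_class = "down"
            else:
                f.true_class = "unchanged"

    ko_mass = sum(f.ko_fraction for f in truth.features)
    if ko_mass > 0.99:
        raise SimulationError(
            f"expected KO feature mass {ko_mass:.3f} exceeds library capacity; "
            "lower sdrna_wt_mass_fraction or sdrna_ko_ratio_mean"
        )


def _emit_read(
    rng: np.random.Generator,
    host_seq: str,
    start: int,
    end: int,
    jitter: int,
    error_rate: float,
) -> str:
    L = len(host_seq)
    if jitter:
        s = start + int(rng.integers(-jitter, jitter + 1))
        e = end + int(rng.integers(-jitter, jitter + 1))
    else:
        s, e = start, end
    s = max(0, min(s, L - 16))
    e = max(s + 16, min(e, L))
    if e - s > 32:
        e = s + 32
    seq = host_seq[s:e]
    if error_rate and rng.random() < error_rate:
        pos = int(rng.integers(0, len(seq)))
        alt = str(rng.choice(_BASES[_BASES != seq[pos]]))
        seq = seq[:pos] + alt + seq[pos + 1 :]
    return seq


def _background_read(rng: np.random.Generator, refset: ReferenceSet) -> str:
    while True:
        n = int(rng.integers(16, 33))
        seq = _random_seq(rng, n)
        if not refset.find(seq):
            return seq


@dataclass
class SimResult:
    wt_fastq: Path
    ko_fastq: Path
    truth: TruthTable
    reference_fasta: Path | None = None
    annotations_tsv: Path | None = None
    truth_tsv: Path | None = None
    config_json: Path | None = None


def simulate_libraries(
    refset: ReferenceSet,
    truth: TruthTable,
    config: SimConfig,
    out_dir: str | Path,
) -> SimResult:
    """Sample the WT and KO FASTQ libraries and realize the truth table.

    Per-library read totals are exact (multinomial over features plus
    background), so RPM denominators equal ``reads_per_library`` in both
    libraries and configured ratios are expected RPM ratios. In the KO
    library the mass lost from collapsed miRNAs (and gained by sdRNAs) is
    balanced by the background component.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # independent stream from the reference stream, still seed-derived
    rng = np.random.default_rng((config.seed, 1))
    _assign_abundances(truth, config, rng)

    R = config.reads_per_library
    feats = truth.features
    p_wt = np.array([f.wt_fraction for f in feats] + [config.background_fraction])
    p_ko_feat = np.array([f.ko_fraction for f in feats])
    p_ko = np.append(p_ko_feat, 1.0 - p_ko_feat.sum())
    counts_wt = rng.multinomial(R, p_wt / p_wt.sum())
    counts_ko = rng.multinomial(R, p_ko / p_ko.sum())

    paths = {}
    for lib, counts in (("WT", counts_wt), ("KO", counts_ko)):
        path = out_dir / f"{lib.lower()}.fastq.gz"
        paths[lib] = path
        # mtime=0 keeps the gzip container byte-reproducible across runs
        with open(path, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as gz, io.TextIOWrapper(gz) as out:
            idx = 0
            for f, c in zip(feats, counts[:-1]):
                host_seq = refset[f.host_id].sequence
                if lib == "WT":
                    f.count_wt = int(c)
                else:
                    f.count_ko = int(c)
                for _ in range(int(c)):
                    seq = _emit_read(
                        rng, host_seq, f.start, f.end,
                        config.end_jitter, config.error_rate,
                    )
                    out.write(f"@{lib}_{idx:08d}\n{seq}\n+\n{'I' * len(seq)}\n")
                    idx += 1
            for _ in range(int(counts[-1])):
                seq = _background_read(rng, refset)
                out.write(f"@{lib}_{idx:08d}\n{seq}\n+\n{'I' * len(seq)}\n")
                idx += 1

    truth_tsv = out_dir / "truth.tsv"
    truth.write_tsv(truth_tsv)
    config_json = out_dir / "sim_config.json"
    with open(config_json, "w") as out:
        json.dump(asdict(config), out, indent=2, default=list)
    return SimResult(
        wt_fastq=paths["WT"],
        ko_fastq=paths["KO"],
        truth=truth,
        truth_tsv=truth_tsv,
        config_json=config_json,
    )


def write_simulated_reference(
    refset: ReferenceSet, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the simulated reference as miRNA/snoRNA FASTAs + arm TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mirna_fa = out_dir / "mirna.fasta"
    snorna_fa = out_dir / "snorna.fasta"
    arms_tsv = out_dir / "mature_arms.tsv"
    with open(mirna_fa, "w") as mi, open(snorna_fa, "w") as sn, open(
        arms_tsv, "w"
    ) as arms:
        arms.write("hairpin_id\tarm_name\tstart\tend\n")
        for rec in refset:
            if rec.biotype is Biotype.SNORNA:
                sn.write(f">{rec.id}\n{rec.sequence}\n")
            else:
                mi.write(f">{rec.id}\n{rec.sequence}\n")
                for arm in rec.mature_annotations:
                    arms.write(f"{rec.id}\t{arm.name}\t{arm.start}\t{arm.end}\n")
    return mirna_fa, snorna_fa


def simulate(config: SimConfig, out_dir: str | Path) -> tuple[ReferenceSet, SimResult]:
    """Convenience wrapper: reference + libraries + all on-disk artifacts."""
    refset, truth = simulate_reference(config)
    mirna_fa, snorna_fa = write_simulated_reference(refset, out_dir)
    result = simulate_libraries(refset, truth, config, out_dir)
    result.reference_fasta = mirna_fa
    result.annotations_tsv = Path(out_dir) / "mature_arms.tsv"
    return refset, result
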