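"""End-to-end orchestration: reference -> align -> profile -> call -> quantify
-> classify -> summarize, with a deterministic artifact manifest.

sdRNA loci are called on the *pooled* WT+KO alignments so both libraries are
quantified over one shared feature set (a locus expressed only after DICER
loss would otherwise be invisible in WT and could not be placed on a common
axis). Counting is then strictly per library.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import aligner, caller, coverage, differential, quantify
from .quantify import DenominatorMode, FeatureType
from .reference import Biotype, ReferenceSet, load_reference

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mirna_fasta: Path
    snorna_fasta: Path
    wt_reads: Path
    ko_reads: Path
    out_dir: Path
    annotations: Path | None = None
    floor: float = 30.0  # RPM; feature kept if reached in either library
    up_threshold: float = 150.0  # percent-of-WT
    down_threshold: float = 50.0
    caller_params: caller.CallerParams = field(default_factory=caller.CallerParams)
    denominator_mode: DenominatorMode = DenominatorMode.TOTAL_READS
    antisense: bool = False
    partial: bool = False
    fractional: bool = False

    def validate(self) -> None:
        if not (0 < self.down_threshold < 100 < self.up_threshold):
            raise ValueError(
                "thresholds must satisfy 0 < down < 100 < up (percent-of-WT)"
            )


@dataclass
class RunResult:
    summary: differential.SwitchSummary
    records: list[quantify.ExpressionRecord]
    kept: list[quantify.ExpressionRecord]
    calls: list[differential.DifferentialCall]
    loci: list[caller.SdrnaLocus]
    manifest: dict[str, str]  # artifact path -> sha256
    stage_counts: dict[str, int]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, refset: ReferenceSet | None = None) -> RunResult:
    """Execute the full comparison and write the artifact set.

    Any stage failure propagates with the stage named in the exception. A
    pre-loaded ``refset`` may be passed to skip FASTA parsing.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_paths: list[Path] = []

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("load_reference")
        if refset is None:
            refset = load_reference(
                config.mirna_fasta, config.snorna_fasta, config.annotations
            )
        refset.build_index()

        name = stage("align")
        aln_wt = aligner.align_library(
            config.wt_reads, refset, config.antisense, config.partial
        )
        aln_ko = aligner.align_library(
            config.ko_reads, refset, config.antisense, config.partial
        )

        name = stage("profile")
        pooled = aligner.AlignmentSummary(
            total_reads=aln_wt.total_reads + aln_ko.total_reads,
            reads_in_length_band=aln_wt.reads_in_length_band + aln_ko.reads_in_length_band,
            reads_aligned=aln_wt.reads_aligned + aln_ko.reads_aligned,
            multimapped_reads=aln_wt.multimapped_reads + aln_ko.multimapped_reads,
            alignments=aln_wt.alignments + aln_ko.alignments,
        )
        profiles = coverage.build_profiles(pooled, refset, config.fractional)
        sno_profiles = {
            pid: p
            for pid, p in profiles.items()
            if refset[pid].biotype is Biotype.SNORNA
        }

        name = stage("call_loci")
        loci = caller.call_all(sno_profiles, config.caller_params)
        loci_bed = out / "sdrna_loci.bed"
        loci_tsv = out / "sdrna_loci.tsv"
        caller.write_loci_bed(loci, loci_bed)
        caller.write_loci_tsv(loci, loci_tsv)
        manifest_paths += [loci_bed, loci_tsv]

        name = stage("quantify")
        features = quantify.build_features(refset, loci)
        records = quantify.quantify(
            features, aln_wt, aln_ko,
            denominator_mode=config.denominator_mode,
            fractional=config.fractional,
            offset_tolerance=config.caller_params.offset_tolerance,
        )
        kept = quantify.apply_floor(records, config.floor)
        expr_tsv = out / "expression.tsv"
        quantify.write_expression_tsv(
            records, {r.feature_id for r in kept}, expr_tsv
        )
        manifest_paths.append(expr_tsv)

        name = stage("classify")
        calls = [
            differential.classify(r, config.up_threshold, config.down_threshold)
            for r in kept
        ]
        calls_tsv = out / "calls.tsv"
        differential.write_calls_tsv(calls, calls_tsv)
        manifest_paths.append(calls_tsv)

        name = stage("summarize")
        summary = differential.summarize(calls)
        differential.add_ratio_of_sums(summary, calls, kept)
        summary_json = out / "summary.json"
        with open(summary_json, "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        for ftype in FeatureType:
            cs = summary.per_type[ftype]
            pairs = cs.top_down if ftype is FeatureType.MIRNA else cs.top_up
            top_tsv = out / f"top10_{'down' if ftype is FeatureType.MIRNA else 'up'}_{ftype.value}.tsv"
            with open(top_tsv, "w") as fh:
                fh.write("feature_id\tpercent_of_wt\n")
                for fid, pct in pairs:
                    fh.write(f"{fid}\t{'inf' if pct == float('inf') else f'{pct:.6g}'}\n")
            manifest_paths.append(top_tsv)
        manifest_paths.append(summary_json)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    stage_counts = {
        "reference_records": len(refset),
        "wt_total_reads": aln_wt.total_reads,
        "ko_total_reads": aln_ko.total_reads,
        "wt_reads_aligned": aln_wt.reads_aligned,
        "ko_reads_aligned": aln_ko.reads_aligned,
        "profiled_precursors": len(profiles),
        "sdrna_loci": len(loci),
        "features": len(features),
        "features_expressed": len(kept),
    }
    manifest = {str(p.relative_to(out)): _sha256(p) for p in manifest_paths}
    manifest["_stage_counts"] = stage_counts  # type: ignore[assignment]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest_hashes = {k: v for k, v in manifest.items() if k != "_stage_counts"}
    return RunResult(
        summary=summary,
        records=records,
        kept=kept,
        calls=calls,
        loci=loci,
        manifest=manifest_hashes,
        stage_counts=stage_counts,
    )
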