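"""End-to-end orchestration: QC -> mapping -> RPKM -> DGE screen.

The pipeline mirrors the analysis order of a two-library tag-profiling
study.  Inputs are either raw FASTQ files per library plus a unigene
reference (the full path), or a pre-computed joint count table (the short
path, starting at the exact test).  Every run writes its resolved
configuration and a machine-readable report next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tagdge import dge_test, read_qc, tag_mapping
from tagdge.dge_test import format_dge_table, run_dge
from tagdge.read_qc import QcThresholds, filter_fastq, read_fastq
from tagdge.tag_mapping import (
    build_gene_profiles,
    map_reads,
    profiles_to_frame,
    read_reference_fasta,
    summarize_mapping,
)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("tagdge")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run.

    Exactly one of (``reads_full`` + ``reads_empty`` + ``reference``) or
    ``counts`` must be provided.  ``n1``/``n2`` override the library
    totals used as RPKM and test denominators; when reads are mapped they
    default to each library's total mapped reads.
    """

    outdir: str = "tagdge_out"
    reads_full: str | None = None
    reads_empty: str | None = None
    reference: str | None = None
    counts: str | None = None
    n1: int | None = None
    n2: int | None = None
    max_unknown_frac: float = 0.05
    low_qual_cutoff: int = 10
    max_low_qual_frac: float = 0.20
    adaptor_seqs: list[str] = field(default_factory=list)
    phred_offset: int = 33
    max_mismatch: int = 2
    fdr_max: float = dge_test.FDR_MAX
    min_abs_log2: float = dge_test.MIN_ABS_LOG2
    rpkm_floor: float = dge_test.RPKM_FLOOR
    seed: int = 0

    def validate(self) -> None:
        from_reads = all(
            v is not None for v in (self.reads_full, self.reads_empty, self.reference)
        )
        if not from_reads and self.counts is None:
            raise ValueError(
                "provide either reads_full+reads_empty+reference or counts"
            )
        if self.counts is not None and self.n1 is None:
            raise ValueError("n1 and n2 are required when starting from counts")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")
        if self.min_abs_log2 < 0 or self.rpkm_floor <= 0:
            raise ValueError("min_abs_log2 must be >= 0 and rpkm_floor > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def _qc_and_map(config: PipelineConfig, label: str, reads_path: str, reference, outdir: Path):
    thresholds = QcThresholds(
        max_unknown_frac=config.max_unknown_frac,
        low_qual_cutoff=config.low_qual_cutoff,
        max_low_qual_frac=config.max_low_qual_frac,
        adaptor_seqs=tuple(config.adaptor_seqs),
    )
    try:
        raw = list(read_fastq(reads_path, config.phred_offset))
        kept, qc_summary = filter_fastq(raw, thresholds)
    except Exception as exc:
        raise StageError("qc", f"{label}: {exc}") from exc
    logger.info("qc[%s]: %d reads in, %d clean", label, qc_summary.total_reads, qc_summary.clean_reads)
    qc_summary.to_json(outdir / f"qc_{label}.json")
    try:
        hits = map_reads([r.bases for r in kept], reference, config.max_mismatch)
        map_summary = summarize_mapping(hits, [len(r) for r in kept])
        profiles = build_gene_profiles(hits, reference, [len(r) for r in kept])
    except Exception as exc:
        raise StageError("map", f"{label}: {exc}") from exc
    logger.info("map[%s]: %d mapped of %d", label, map_summary.total_mapped, map_summary.total_reads)
    map_summary.to_json(outdir / f"map_{label}.json")
    counts = profiles_to_frame(profiles)
    counts.to_csv(outdir / f"counts_{label}.tsv", sep="\t", index=False)
    return qc_summary, map_summary, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"outdir": str(outdir), "stages": []}

    if config.counts is not None:
        try:
            joint = pd.read_csv(config.counts, sep="\t")
        except Exception as exc:
            raise StageError("load_counts", str(exc)) from exc
        n1, n2 = config.n1, config.n2
    else:
        reference = read_reference_fasta(config.reference)
        per_lib = {}
        for label, reads_path in (("full", config.reads_full), ("empty", config.reads_empty)):
            qc_s, map_s, counts = _qc_and_map(config, label, reads_path, reference, outdir)
            per_lib[label] = (qc_s, map_s, counts)
            report[f"qc_{label}"] = qc_s.to_dict()
            report[f"mapping_{label}"] = map_s.to_dict()
        report["stages"] += ["qc", "map"]
        joint = per_lib["full"][2].merge(
            per_lib["empty"][2],
            on=["gene_id", "length"],
            suffixes=("_full", "_empty"),
        ).rename(columns={"count_full": "count_full", "count_empty": "count_empty"})
        joint = joint[["gene_id", "length", "count_full", "count_empty"]]
        n1 = config.n1 or per_lib["full"][1].total_mapped
        n2 = config.n2 or per_lib["empty"][1].total_mapped

    if joint.empty:
        report["stages"].append("dgetest")
        report.update({"n_genes": 0, "n_up": 0, "n_down": 0, "n1": n1, "n2": n2})
        (outdir / "deg.tsv").write_text("")
    else:
        try:
            deg = run_dge(
                joint, n1, n2,
                fdr_max=config.fdr_max,
                min_abs_log2=config.min_abs_log2,
                rpkm_floor=config.rpkm_floor,
            )
        except Exception as exc:
            raise StageError("dgetest", str(exc)) from exc
        format_dge_table(deg).to_csv(outdir / "deg.tsv", sep="\t", index=False)
        n_up = int((deg["direction"] == "Up").sum())
        n_down = int((deg["direction"] == "Down").sum())
        logger.info("dgetest: %d genes, %d up, %d down", len(deg), n_up, n_down)
        report["stages"].append("dgetest")
        report.update(
            {"n_genes": int(len(deg)), "n_up": n_up, "n_down": n_down,
             "n1": int(n1), "n2": int(n2)}
        )
    report["artifacts"] = sorted(str(p) for p in outdir.iterdir())
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
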