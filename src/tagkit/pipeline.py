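"""End-to-end pipeline: filter, assemble, correct, annotate, quantify, fuse.

The stage defaults collected in :class:`PipelineConfig` are the method's
published operating point: sliding windows h=250/t=100, combination penalties
mu=(2,2,1,1) with the 1000 cross-chromosome distance, overlap penalties
theta=(0.5,0.5), DIU thresholds Q=4 and P=5%, the >=2-CCS input filter, the
100-bp FSM end window and the 20-bp fusion segment minimum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import annotate as annotate_mod
from . import fusion as fusion_mod
from . import hybrid_align, quantify, splice_correct
from .refio import load_annotation, load_genome
from .simulate import load_reads_fasta

log = logging.getLogger("tagkit")


@dataclass
class PipelineConfig:
    reads_fasta: str = ""
    genome_fasta: str = ""
    gtf: str = ""
    long_sam: str = ""
    short_sam: Optional[str] = None
    model_path: Optional[str] = None
    out_dir: str = "tagkit_out"
    use_cnn: bool = True  # False reproduces the deterministic no-CNN mode
    window: int = 250
    step: int = 100
    mu: tuple[float, float, float, float] = (2.0, 2.0, 1.0, 1.0)
    theta: tuple[float, float] = (0.5, 0.5)
    q_threshold: float = 4.0
    p_threshold: float = 0.05
    min_ccs: int = 2
    fsm_end_window: int = 100
    fusion_min_seg: int = 20
    xchrom_dist: float = 1000.0
    min_intron: int = 20
    correction_radius: int = 15
    bp_tol: int = 10
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        for key in ("mu", "theta"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    outputs: dict[str, str]
    alignments: list = field(default_factory=list)
    records: list = field(default_factory=list)
    expression: Optional[quantify.ExpressionTable] = None
    fusion_calls: list = field(default_factory=list)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the output bundle.

    Outputs: corrected alignments (BED12), the per-read junction text file,
    gene and transcript expression tables, the gene-fusion table and a
    manifest with content hashes."""
    for path in (config.reads_fasta, config.genome_fasta, config.gtf, config.long_sam):
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"missing pipeline input: {path!r}")
    if config.short_sam and not os.path.exists(config.short_sam):
        raise FileNotFoundError(f"missing pipeline input: {config.short_sam!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    stages: list[tuple[str, float, int]] = []

    def stage(name: str, t0: float, count: int):
        stages.append((name, time.perf_counter() - t0, count))
        log.info("stage %s: %d records (%.2fs)", name, count, time.perf_counter() - t0)

    t0 = time.perf_counter()
    genome = load_genome(config.genome_fasta)
    db = load_annotation(config.gtf, genome)
    reads = load_reads_fasta(config.reads_fasta)
    stage("load", t0, len(reads))

    t0 = time.perf_counter()
    retained = quantify.filter_ccs(reads, config.min_ccs)
    stage("ccs_filter", t0, len(retained))

    t0 = time.perf_counter()
    long_map = hybrid_align.read_sam(config.long_sam)
    short_map = hybrid_align.read_sam(config.short_sam) if config.short_sam else {}
    alignments = []
    for read in retained:
        aln = hybrid_align.assemble_alignment(
            read,
            long_map.get(read.read_id, []),
            short_map.get(read.read_id, []),
            mu=config.mu,
            xchrom_dist=config.xchrom_dist,
            min_intron=config.min_intron,
        )
        if aln.is_mapped:
            alignments.append(aln)
    stage("assemble", t0, len(alignments))

    t0 = time.perf_counter()
    model = None
    if config.use_cnn and config.model_path:
        model = splice_correct.SpliceModel.load(config.model_path)
    corrected = [
        splice_correct.correct_alignment(model, genome, db, aln, config.correction_radius)
        for aln in alignments
    ]
    stage("correct", t0, len(corrected))

    t0 = time.perf_counter()
    ccs_counts = {r.read_id: r.ccs_count for r in retained}
    records = annotate_mod.annotate_all(
        corrected, db, genome, ccs_counts,
        theta=config.theta,
        fsm_end_window=config.fsm_end_window,
        fusion_min_segment=config.fusion_min_seg,
    )
    stage("annotate", t0, len(records))

    t0 = time.perf_counter()
    table = quantify.build_expression_table(
        "sample", records, db, total_transcripts=len(retained)
    )
    stage("quantify", t0, len(table.isoform_counts) + len(table.novel_counts))

    t0 = time.perf_counter()
    calls = fusion_mod.call_fusions(records, config.bp_tol)
    stage("fusion", t0, len(calls))

    out = {
        "bed": os.path.join(config.out_dir, "corrected_alignments.bed"),
        "junctions": os.path.join(config.out_dir, "junctions.txt"),
        "annotation": os.path.join(config.out_dir, "annotation.tsv"),
        "gene_expression": os.path.join(config.out_dir, "gene_expression.tsv"),
        "transcript_expression": os.path.join(config.out_dir, "transcript_expression.tsv"),
        "fusions": os.path.join(config.out_dir, "fusions.tsv"),
    }
    hybrid_align.write_bed12(corrected, out["bed"])
    hybrid_align.write_junction_file(corrected, out["junctions"])
    annotate_mod.write_annotation_tsv(records, out["annotation"])
    quantify.write_expression_tsv(table, db, out["gene_expression"], out["transcript_expression"])
    fusion_mod.write_fusion_tsv(calls, out["fusions"])
    manifest = {
        "stages": [{"name": n, "seconds": round(s, 3), "records": c} for n, s, c in stages],
        "outputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in out.items()},
        "config": dataclasses.asdict(config),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    out["manifest"] = manifest_path
    return PipelineResult(out, corrected, records, table, calls)
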