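"""Desk-scale evaluation protocols run end to end on synthetic worlds.

Each protocol generates its own inputs from a seed, runs the relevant pipeline
stages and returns the measured quantities.  Problem sizes are chosen to run
in minutes on one CPU; every size is a keyword so larger runs are one call
away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import annotate as annotate_mod
from . import fusion as fusion_mod
from . import hybrid_align, quantify, splice_correct
from .simulate import (FusionSimConfig, WorldConfig, corrupt_junctions,
                       delete_annotation, make_world, sensitivity_precision,
                       simulate_fusions, simulate_reads, truth_alignment)


def _group_records(records):
    long_map: dict[str, list] = {}
    for r in records:
        long_map.setdefault(r.query_name.rsplit("|", 1)[0], []).append(r)
    return long_map


def splice_model_validation(
    seed: int = 7,
    n_genes: int = 100,
    samples_per_site: int = 5,
    epochs: int = 60,
    repeats: int = 2,
) -> dict:
    """Train the splice-boundary CNN on a synthetic annotation and report
    argmax accuracy on the held-out 10% validation windows."""
    world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    train, val = splice_correct.build_training_set(
        world.db, world.genome, seed=seed, samples_per_site=samples_per_site
    )
    model = splice_correct.train_model(train, epochs=epochs, repeats=repeats, seed=seed)
    return {
        "accuracy": model.accuracy(val),
        "n_train": len(train),
        "n_validation": len(val),
        "model": model,
        "world": world,
    }


def noise_free_round_trip(
    seed: int = 0,
    n_genes: int = 50,
    n_reads: int = 150,
) -> dict:
    """Error-free reads through assembly + fallback correction + annotation:
    fraction of truth junctions recovered and of full-length reads called FSM."""
    world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    sim = simulate_reads(world, n_reads=n_reads, seed=seed + 1)
    long_map = _group_records(sim.long_records)
    short_map = _group_records(sim.short_records)
    junc_total = junc_ok = fsm_total = fsm_ok = 0
    for read in sim.reads:
        truth = sim.truths[read.read_id]
        aln = hybrid_align.assemble_alignment(
            read, long_map[read.read_id], short_map.get(read.read_id, [])
        )
        corrected = splice_correct.correct_alignment(None, world.genome, world.db, aln)
        got = {j.key for j in corrected.junctions}
        junc_total += len(truth.junction_keys)
        junc_ok += len(got & truth.junction_keys)
        if truth.truth_class == "FSM":
            fsm_total += 1
            rec = annotate_mod.classify(corrected, world.db, world.genome)
            fsm_ok += rec.tclass == "FSM"
    return {
        "junction_recovery": junc_ok / junc_total if junc_total else float("nan"),
        "fsm_rate": fsm_ok / fsm_total if fsm_total else float("nan"),
        "n_reads": len(sim.reads),
        "n_truth_junctions": junc_total,
    }


def correction_benefit(
    seed: int = 0,
    n_genes: int = 50,
    n_reads: int = 120,
    max_shift: int = 5,
    model: splice_correct.SpliceModel | None = None,
    world=None,
) -> dict:
    """Wobble-shift truth junctions by up to ±max_shift, then measure the
    exact-recovery fraction with and without the correction stage."""
    if world is None:
        world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    sim = simulate_reads(world, n_reads=n_reads, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    total = ok_without = ok_with = shifted_total = 0
    for read in sim.reads:
        truth = sim.truths[read.read_id]
        if not truth.junction_keys:
            continue
        corrupted, shifted = corrupt_junctions(
            world.genome, truth_alignment(truth), rng, max_shift
        )
        corrected = splice_correct.correct_alignment(
            model, world.genome, world.db, corrupted, radius=max_shift
        )
        total += len(truth.junction_keys)
        shifted_total += shifted
        ok_without += len({j.key for j in corrupted.junctions} & truth.junction_keys)
        ok_with += len({j.key for j in corrected.junctions} & truth.junction_keys)
    return {
        "recovery_with": ok_with / total,
        "recovery_without": ok_without / total,
        "n_junctions": total,
        "n_shifted": shifted_total,
    }


def annotation_deletion(
    seed: int = 0,
    x_percent: float = 10.0,
    n_genes: int = 60,
    reads_per_isoform: int = 2,
) -> dict:
    """Delete X% of genes from the annotation, realign error-free reads from
    the full transcriptome against the reduced reference and score rediscovery
    of the deleted genes' junctions.

    Reported junctions are the corrected junction calls absent from the
    reduced annotation (kept-gene junctions are known, hence not reported)."""
    world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    reduced, positives, _removed = delete_annotation(world.db, x_percent, seed + 1)
    expression = {iso: reads_per_isoform for iso in world.db.isoforms}
    sim = simulate_reads(world, seed=seed + 2, expression=expression)
    long_map = _group_records(sim.long_records)
    short_map = _group_records(sim.short_records)
    reported: set[tuple[str, int, int]] = set()
    for read in sim.reads:
        aln = hybrid_align.assemble_alignment(
            read, long_map[read.read_id], short_map.get(read.read_id, [])
        )
        corrected = splice_correct.correct_alignment(None, world.genome, reduced, aln)
        for j in corrected.junctions:
            if j.key not in reduced.junction_set:
                reported.add(j.key)
    counts = sensitivity_precision(reported, positives)
    return {
        "sensitivity": counts.sensitivity,
        "precision": counts.precision,
        "counts": counts,
        "n_positives": counts.tp + counts.fn,
    }


@dataclass
class FusionProtocolResult:
    sensitivity_ge2: float
    background_calls: int
    n_truth: int
    n_truth_ge2: int
    somatic_kept: int
    somatic_expected: int
    germline_removed: bool


def fusion_protocol(
    seed: int = 0,
    n_genes: int = 40,
    n_fusions: int = 40,
    n_background: int = 300,
    error_free: bool = True,
) -> FusionProtocolResult:
    """Fusion detection on one simulated dataset: call fusions from assembled
    annotations, score sensitivity on truths with >=2 supporting reads and
    count calls arising from background transcripts; then exercise the somatic
    filter with an empty and a fusion-bearing matched normal."""
    world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    cfg = FusionSimConfig(
        n_datasets=1, n_fusions=n_fusions, n_background=n_background,
        sub_rate=0.0 if error_free else 0.005,
        ins_rate=0.0 if error_free else 0.001,
        del_rate=0.0 if error_free else 0.001,
    )
    ds = simulate_fusions(world, cfg, seed=seed + 1)[0]
    long_map = _group_records(ds.long_records)
    records = []
    for read in ds.reads:
        aln = hybrid_align.assemble_alignment(read, long_map[read.read_id])
        if aln.is_mapped:
            records.append(annotate_mod.classify(
                aln, world.db, world.genome, ccs_count=read.ccs_count))
    calls = fusion_mod.call_fusions(records)

    def matching_call(truth):
        return next((c for c in calls if c.matches(
            truth.gene5, truth.gene3, truth.breakpoint5, truth.breakpoint3,
            fusion_mod.DEFAULT_BP_TOL)), None)

    truths_ge2 = [t for t in ds.truths if t.n_supporting >= 2]
    detected = sum(1 for t in truths_ge2 if matching_call(t) is not None)
    fusion_read_ids = {rid for t in ds.truths for rid in t.read_ids}
    background_calls = sum(
        1 for c in calls if any(rid not in fusion_read_ids for rid, _ in c.supporters)
    )
    # somatic filtering: no normal support -> every CCS>=2-backed call kept
    somatic = fusion_mod.somatic_filter(calls, normal_records=[])
    expected = sum(1 for c in calls if c.max_ccs >= 2)
    # a normal sample containing the first truth fusion removes exactly it
    germline_removed = True
    if ds.truths:
        t0 = ds.truths[0]
        normal = [r for r in records if r.read_id in set(t0.read_ids)]
        filtered = fusion_mod.somatic_filter(calls, normal)
        c0 = matching_call(t0)
        germline_removed = c0 is None or all(
            not f.matches(t0.gene5, t0.gene3, t0.breakpoint5, t0.breakpoint3,
                          fusion_mod.DEFAULT_BP_TOL)
            for f in filtered
        )
    return FusionProtocolResult(
        sensitivity_ge2=detected / len(truths_ge2) if truths_ge2 else float("nan"),
        background_calls=background_calls,
        n_truth=len(ds.truths),
        n_truth_ge2=len(truths_ge2),
        somatic_kept=len(somatic),
        somatic_expected=expected,
        germline_removed=germline_removed,
    )


def technical_replicate_diu(
    seed: int = 0,
    n_genes: int = 40,
    n_reads: int = 400,
) -> dict:
    """Self-vs-self DIU comparison: two read samples drawn from one expression
    profile must yield no gene at FDR < 0.05."""
    world = make_world(WorldConfig(n_genes=n_genes), seed=seed)
    rng = np.random.default_rng(seed + 1)
    iso_ids = sorted(world.db.isoforms)
    weights = rng.dirichlet(np.ones(len(iso_ids)) * 0.8)
    tables = []
    for rep, rep_seed in enumerate((seed + 10, seed + 11)):
        rep_rng = np.random.default_rng(rep_seed)
        picks = rep_rng.choice(len(iso_ids), size=n_reads, p=weights)
        expression = {}
        for k in picks:
            expression[iso_ids[k]] = expression.get(iso_ids[k], 0) + 1
        sim = simulate_reads(world, seed=rep_seed, expression=expression)
        long_map = _group_records(sim.long_records)
        short_map = _group_records(sim.short_records)
        records = []
        for read in sim.reads:
            aln = hybrid_align.assemble_alignment(
                read, long_map[read.read_id], short_map.get(read.read_id, []))
            corrected = splice_correct.correct_alignment(None, world.genome, world.db, aln)
            records.append(annotate_mod.classify(corrected, world.db, world.genome))
        tables.append(quantify.build_expression_table(
            f"rep{rep}", records, world.db, total_transcripts=len(sim.reads)))
    diu_tables = quantify.build_diu_tables(tables[0], tables[1], world.db)
    results = quantify.diu_test(diu_tables, seed=seed)
    n_hits = sum(1 for r in results if r.qvalue < 0.05)
    return {"n_tested": len(results), "n_diu": n_hits}
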