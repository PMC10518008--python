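"""Expression counting, TPT normalisation, differential expression and DIU.

A read counts toward a known isoform only when its junction chain matches
consecutive junctions of exactly one isoform; ambiguous reads are excluded.
Novel (NIC/NNC) reads are clustered by junction-chain containment within their
class.  Expression is reported as TPT (transcripts per hundred thousand):
count x 100,000 / total retained transcripts of the sample.  Differential
isoform usage is a per-gene isoform-by-condition exact test (Fisher for 2x2,
exact multivariate-hypergeometric enumeration or seeded Monte Carlo beyond)
after the low-expression filters, with Benjamini-Hochberg FDR across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import AnnotationRecord
from .hybrid_align import LongRead
from .refio import IsoformDB

DEFAULT_MIN_CCS = 2
DEFAULT_Q = 4.0
DEFAULT_P = 0.05
TPT_SCALE = 100_000.0


def filter_ccs(reads: Sequence[LongRead], min_ccs: int = DEFAULT_MIN_CCS) -> list[LongRead]:
    """Keep transcripts supported by at least ``min_ccs`` CCS reads."""
    return [r for r in reads if r.ccs_count >= min_ccs]


def tpt(count: float, total: int) -> float:
    if total <= 0:
        raise ValueError("total transcript count must be positive")
    return count * TPT_SCALE / total


def _is_subchain(sub: Sequence, full: Sequence) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(tuple(full[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def count_known(
    records: Sequence[AnnotationRecord],
    db: IsoformDB,
    ccs_weighted: bool = False,
) -> tuple[dict[str, int], dict[str, int]]:
    """Observed transcript counts per known isoform and per gene.

    An FSM/ISM read is counted for an isoform iff its junction chain matches
    consecutive junctions of only that isoform; multi-hit reads are dropped
    from expression.  Monoexonic FSM/ISM reads count toward their best match
    (the chain-uniqueness rule is vacuous with zero junctions).  Gene counts
    are the sum over the gene's known isoforms."""
    chains = {
        iso_id: tuple(j.key for j in iso.junctions)
        for iso_id, iso in db.isoforms.items()
    }
    by_junction: dict[tuple, list[str]] = {}
    for iso_id, chain in chains.items():
        for key in chain:
            by_junction.setdefault(key, []).append(iso_id)
    iso_counts: dict[str, int] = {}
    for rec in records:
        if rec.tclass not in ("FSM", "ISM"):
            continue
        weight = rec.ccs_count if ccs_weighted else 1
        chain = rec.junction_keys
        if not chain:
            if rec.best_match is not None:
                iso_counts[rec.best_match] = iso_counts.get(rec.best_match, 0) + weight
            continue
        cands = set(by_junction.get(chain[0], []))
        hits = [i for i in cands if _is_subchain(chain, chains[i])]
        if len(hits) == 1:
            iso_counts[hits[0]] = iso_counts.get(hits[0], 0) + weight
    gene_counts: dict[str, int] = {}
    for iso_id, c in iso_counts.items():
        gid = db.isoforms[iso_id].gene_id
        gene_counts[gid] = gene_counts.get(gid, 0) + c
    return iso_counts, gene_counts


@dataclass
class NovelCluster:
    cluster_id: str
    tclass: str
    chain: tuple
    members: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


def cluster_novel(records: Sequence[AnnotationRecord]) -> list[NovelCluster]:
    """Cluster NIC/NNC reads by junction-chain containment within their class.

    Reads are taken in descending junction-count order (ties by read id) so
    every cluster representative contains its members' chains as consecutive
    sub-chains; assignment to the earliest matching cluster is deterministic."""
    novel = [r for r in records if r.tclass in ("NIC", "NNC") and r.junctions]
    novel.sort(key=lambda r: (-len(r.junctions), r.read_id))
    clusters: list[NovelCluster] = []
    counter = {"NIC": 0, "NNC": 0}
    for rec in novel:
        chain = rec.junction_keys
        target = None
        for cl in clusters:
            if cl.tclass == rec.tclass and _is_subchain(chain, cl.chain):
                target = cl
                break
        if target is None:
            counter[rec.tclass] += 1
            target = NovelCluster(f"novel_{rec.tclass}_{counter[rec.tclass]}",
                                  rec.tclass, chain)
            clusters.append(target)
        target.members.append(rec.read_id)
    return clusters


@dataclass
class ExpressionTable:
    """Per-feature counts and TPT for one sample."""

    sample_id: str
    total_transcripts: int
    isoform_counts: dict[str, int]
    gene_counts: dict[str, int]
    novel_counts: dict[str, int]

    def isoform_tpt(self, feature: str) -> float:
        return tpt(self.isoform_counts.get(feature, 0), self.total_transcripts)

    def gene_tpt(self, gene: str) -> float:
        return tpt(self.gene_counts.get(gene, 0), self.total_transcripts)

    def all_feature_tpt(self) -> dict[str, float]:
        out = {f: tpt(c, self.total_transcripts) for f, c in self.isoform_counts.items()}
        out.update({f: tpt(c, self.total_transcripts) for f, c in self.novel_counts.items()})
        return out


def build_expression_table(
    sample_id: str,
    records: Sequence[AnnotationRecord],
    db: IsoformDB,
    total_transcripts: Optional[int] = None,
    ccs_weighted: bool = False,
) -> ExpressionTable:
    iso_counts, gene_counts = count_known(records, db, ccs_weighted)
    clusters = cluster_novel(records)
    total = total_transcripts if total_transcripts is not None else len(records)
    return ExpressionTable(
        sample_id=sample_id,
        total_transcripts=total,
        isoform_counts=iso_counts,
        gene_counts=gene_counts,
        novel_counts={c.cluster_id: c.count for c in clusters},
    )


def write_expression_tsv(table: ExpressionTable, db: IsoformDB, gene_path: str,
                         isoform_path: str) -> None:
    with open(gene_path, "w") as fh:
        fh.write("gene_id\tcount\ttpt\n")
        for gid in sorted(table.gene_counts):
            fh.write(f"{gid}\t{table.gene_counts[gid]}\t{table.gene_tpt(gid):.4f}\n")
    with open(isoform_path, "w") as fh:
        fh.write("feature_id\tgene_id\tclass\tcount\ttpt\n")
        for iso_id in sorted(table.isoform_counts):
            gid = db.isoforms[iso_id].gene_id
            fh.write(f"{iso_id}\t{gid}\tknown\t{table.isoform_counts[iso_id]}\t"
                     f"{table.isoform_tpt(iso_id):.4f}\n")
        for cid in sorted(table.novel_counts):
            cls = "NIC" if "_NIC_" in cid else "NNC"
            c = table.novel_counts[cid]
            fh.write(f"{cid}\t.\t{cls}\t{c}\t{tpt(c, table.total_transcripts):.4f}\n")


def diff_isoform_binomial(count1: int, count2: int, total1: int, total2: int) -> float:
    """Exact two-sided binomial test of a feature's counts in two samples,
    success probability total1/(total1+total2)."""
    if total1 <= 0 or total2 <= 0:
        raise ValueError("totals must be positive")
    n = count1 + count2
    if n == 0:
        return 1.0
    p = total1 / (total1 + total2)
    return float(stats.binomtest(count1, n, p, alternative="two-sided").pvalue)


@dataclass
class DIUTable:
    """Per-gene isoform-by-condition contingency data."""

    gene_id: str
    isoform_ids: list[str]
    counts1: list[int]
    counts2: list[int]
    tpt1: list[float]
    tpt2: list[float]

    @property
    def m(self) -> int:
        return len(self.isoform_ids)


def build_diu_tables(
    table1: ExpressionTable, table2: ExpressionTable, db: IsoformDB
) -> list[DIUTable]:
    out = []
    for gid in sorted(db.genes):
        iso_ids = [i for i in sorted(db.genes[gid])
                   if table1.isoform_counts.get(i, 0) + table2.isoform_counts.get(i, 0) > 0]
        if len(iso_ids) < 2:
            continue
        out.append(DIUTable(
            gene_id=gid,
            isoform_ids=iso_ids,
            counts1=[table1.isoform_counts.get(i, 0) for i in iso_ids],
            counts2=[table2.isoform_counts.get(i, 0) for i in iso_ids],
            tpt1=[table1.isoform_tpt(i) for i in iso_ids],
            tpt2=[table2.isoform_tpt(i) for i in iso_ids],
        ))
    return out


def diu_filter(table: DIUTable, q: float = DEFAULT_Q, p: float = DEFAULT_P) -> bool:
    """Low-expression gene filter on TPT values: both condition sums >= Q, and
    every isoform's two-condition TPT sum >= Q and >= fraction P of the gene's."""
    s1, s2 = sum(table.tpt1), sum(table.tpt2)
    if s1 < q or s2 < q:
        return False
    denom = s1 + s2
    for e1, e2 in zip(table.tpt1, table.tpt2):
        if e1 + e2 < q or (e1 + e2) / denom < p:
            return False
    return True


def _table_logprob(rows: Sequence[tuple[int, int]]) -> float:
    """Log probability of an m x 2 table under fixed margins (multivariate
    hypergeometric null)."""
    n = sum(a + b for a, b in rows)
    c1 = sum(a for a, _ in rows)
    logp = -math.lgamma(n + 1) + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
    for a, b in rows:
        logp += (math.lgamma(a + b + 1) - math.lgamma(a + 1) - math.lgamma(b + 1))
    return logp


def fisher_exact_mx2(
    counts1: Sequence[int],
    counts2: Sequence[int],
    max_exact_tables: int = 500_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher exact test on an m x 2 contingency table.

    2x2 tables use the hypergeometric closed form; larger tables enumerate all
    tables with the observed margins when feasible, summing the probabilities
    of tables no more likely than the observed one, otherwise a seeded Monte
    Carlo estimate of the same tail."""
    rows = [(int(a), int(b)) for a, b in zip(counts1, counts2)]
    row_sums = [a + b for a, b in rows]
    c1 = sum(a for a, _ in rows)
    c2 = sum(b for _, b in rows)
    if c1 == 0 or c2 == 0 or all(s == 0 for s in row_sums):
        return 1.0
    rows = [(a, b) for (a, b) in rows]
    if len(rows) == 2:
        table = np.array(rows)
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    est_tables = 1.0
    for s in row_sums:
        est_tables *= (min(s, c1) + 1)
        if est_tables > max_exact_tables:
            break
    obs_logp = _table_logprob(rows)
    eps = 1e-9
    if est_tables <= max_exact_tables:
        total = 0.0
        def recurse(i: int, remaining: int, acc_logp: float):
            nonlocal total
            if i == len(rows) - 1:
                a = remaining
                if 0 <= a <= row_sums[i]:
                    b = row_sums[i] - a
                    lp = acc_logp + (math.lgamma(row_sums[i] + 1)
                                     - math.lgamma(a + 1) - math.lgamma(b + 1))
                    if lp <= obs_logp_full + eps:
                        total += math.exp(lp)
                return
            for a in range(0, min(row_sums[i], remaining) + 1):
                b = row_sums[i] - a
                recurse(i + 1, remaining - a,
                        acc_logp + math.lgamma(row_sums[i] + 1)
                        - math.lgamma(a + 1) - math.lgamma(b + 1))
        n = sum(row_sums)
        base = -math.lgamma(n + 1) + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
        obs_logp_full = obs_logp
        recurse(0, c1, base)
        return min(1.0, total)
    # Monte Carlo: permute condition labels, compare table probabilities
    rng = np.random.default_rng(seed)
    labels = np.zeros(sum(row_sums), dtype=np.int8)
    labels[:c1] = 1
    row_of = np.repeat(np.arange(len(rows)), row_sums)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        a_counts = np.bincount(row_of[labels == 1], minlength=len(rows))
        sim_rows = [(int(a), s - int(a)) for a, s in zip(a_counts, row_sums)]
        if _table_logprob(sim_rows) <= obs_logp + eps:
            hits += 1
    return (hits + 1) / (n_mc + 1)


@dataclass
class DIUResult:
    gene_id: str
    m: int
    pvalue: float
    qvalue: float = float("nan")
    table: Optional[DIUTable] = None


def diu_test(
    tables: Sequence[DIUTable],
    q: float = DEFAULT_Q,
    p: float = DEFAULT_P,
    seed: int = 0,
) -> list[DIUResult]:
    """Filter genes, run the exact test per gene on the raw counts and adjust
    p-values with Benjamini-Hochberg."""
    kept = [t for t in tables if diu_filter(t, q, p)]
    results = [
        DIUResult(t.gene_id, t.m, fisher_exact_mx2(t.counts1, t.counts2, seed=seed), table=t)
        for t in kept
    ]
    if results:
        qvals = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, qvals):
            r.qvalue = float(qv)
    return results


def write_diu_tsv(results: Sequence[DIUResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tm\tpvalue\tqvalue\tcounts_cond1\tcounts_cond2\n")
        for r in results:
            c1 = ",".join(map(str, r.table.counts1)) if r.table else "."
            c2 = ",".join(map(str, r.table.counts2)) if r.table else "."
            fh.write(f"{r.gene_id}\t{r.m}\t{r.pvalue:.6g}\t{r.qvalue:.6g}\t{c1}\t{c2}\n")
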