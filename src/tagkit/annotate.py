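"""Best-match selection and seven-class transcript classification.

Classes: FSM (all junctions of the best-match isoform, both ends within 100 bp
of its ends, no intron retention), ISM (a consecutive sub-chain of the match's
junctions), NIC (only known donors/acceptors or known junctions in a novel
combination, including retention of a known intron), NNC (at least one novel
donor or acceptor), Genic (monoexonic inside a gene, no reference match),
Intergenic (outside every annotated gene) and Fusion (a transcript whose
segments unambiguously cover two distinct genes, at least 20 bp each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .hybrid_align import SplicedAlignment
from .refio import GenomeRef, IsoformDB, Isoform, Junction, junction_motif

DEFAULT_THETA = (0.5, 0.5)
FSM_END_WINDOW = 100
FUSION_MIN_SEGMENT = 20

CLASSES = ("FSM", "ISM", "NIC", "NNC", "Genic", "Intergenic", "Fusion")


@dataclass
class MatchScore:
    """Exonic-overlap score of a transcript against one reference isoform:
    ``L_TI - theta1 * L_I - theta2 * L_T``."""

    l_ti: int
    l_t: int
    l_i: int
    theta1: float = 0.5
    theta2: float = 0.5

    @property
    def score(self) -> float:
        return self.l_ti - self.theta1 * self.l_i - self.theta2 * self.l_t


@dataclass
class FusionSide:
    gene_id: str
    chrom: str
    breakpoint: int
    strand: str
    mapped_length: int


@dataclass
class AnnotationRecord:
    read_id: str
    tclass: str
    best_match: Optional[str] = None
    match_score: Optional[MatchScore] = None
    genes: list[str] = field(default_factory=list)
    junctions: list[Junction] = field(default_factory=list)
    junction_novelty: list[tuple[bool, bool]] = field(default_factory=list)  # (known, canonical)
    fusion_sides: list[FusionSide] = field(default_factory=list)
    ccs_count: int = 1

    @property
    def junction_keys(self) -> tuple[tuple[str, int, int], ...]:
        return tuple(j.key for j in self.junctions)


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect_len(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    i = j = total = 0
    a, b = _merge(a), _merge(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def best_match(
    aln: SplicedAlignment,
    db: IsoformDB,
    theta: Sequence[float] = DEFAULT_THETA,
) -> Optional[tuple[Isoform, MatchScore]]:
    """Highest-scoring overlapping reference isoform, or None.

    Overlap lengths are computed on exonic bases; ties break toward the
    smaller isoform id for determinism."""
    read_exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    total_read = 0
    for seg in aln.segments:
        read_exons_by_chrom.setdefault(seg.chrom, []).extend(seg.exons)
        total_read += seg.mapped_length
    candidates: dict[str, Isoform] = {}
    for seg in aln.segments:
        s, e = seg.span
        for iso in db.overlapping_isoforms(seg.chrom, s, e):
            candidates[iso.isoform_id] = iso
    best: Optional[tuple[Isoform, MatchScore]] = None
    for iso_id in sorted(candidates):
        iso = candidates[iso_id]
        l_ti = _intersect_len(read_exons_by_chrom.get(iso.chrom, []), iso.exons)
        if l_ti == 0:
            continue
        ms = MatchScore(l_ti, total_read - l_ti, iso.exonic_length - l_ti,
                        theta[0], theta[1])
        if best is None or ms.score > best[1].score:
            best = (iso, ms)
    return best


def label_junction_novelty(
    junction: Junction, db: IsoformDB, genome: Optional[GenomeRef] = None
) -> tuple[bool, bool]:
    """(known-in-reference, canonical-motif) labels for one junction."""
    known = db.is_known_junction(junction)
    canonical = False
    if genome is not None:
        try:
            canonical = junction_motif(genome, junction)[1]
        except (ValueError, KeyError):
            canonical = False
    return known, canonical


def _is_subchain(sub: Sequence, full: Sequence) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(tuple(full[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def _has_intron_retention(aln: SplicedAlignment, iso: Isoform) -> bool:
    for seg in aln.segments:
        if seg.chrom != iso.chrom:
            continue
        for es, ee in seg.exons:
            for j in iso.junctions:
                if es <= j.start and j.end <= ee:
                    return True
    return False


def _fusion_check(
    aln: SplicedAlignment, db: IsoformDB, min_segment: int
) -> Optional[list[FusionSide]]:
    """Fusion: the read's exon blocks, taken in read order, fall into exactly
    two gene groups (a junction or segment break unambiguously spanning two
    distinct genes), with >= ``min_segment`` mapped bases on each side.

    An exon overlapping zero or several genes breaks unambiguity and vetoes
    the call."""
    if aln.n_exons < 2:
        return None
    groups: list[dict] = []
    for seg in sorted(aln.segments, key=lambda s: s.read_start):
        for exon in seg.exons:
            genes = db.overlapping_genes(seg.chrom, exon[0], exon[1])
            gene = genes[0] if len(genes) == 1 else None
            if groups and groups[-1]["gene"] == gene and groups[-1]["chrom"] == seg.chrom:
                groups[-1]["exons"].append(exon)
            else:
                groups.append({"gene": gene, "chrom": seg.chrom,
                               "strand": seg.strand, "exons": [exon]})
    if len(groups) != 2:
        return None
    a, b = groups
    if a["gene"] is None or b["gene"] is None or a["gene"] == b["gene"]:
        return None
    len_a = sum(e - s for s, e in a["exons"])
    len_b = sum(e - s for s, e in b["exons"])
    if len_a < min_segment or len_b < min_segment:
        return None
    # breakpoints: the exon edges facing the gene switch, in read order
    return [
        FusionSide(a["gene"], a["chrom"], a["exons"][-1][1], a["strand"], len_a),
        FusionSide(b["gene"], b["chrom"], b["exons"][0][0], b["strand"], len_b),
    ]


def classify(
    aln: SplicedAlignment,
    db: IsoformDB,
    genome: Optional[GenomeRef] = None,
    theta: Sequence[float] = DEFAULT_THETA,
    fsm_end_window: int = FSM_END_WINDOW,
    fusion_min_segment: int = FUSION_MIN_SEGMENT,
    ccs_count: int = 1,
) -> AnnotationRecord:
    """Assign exactly one of the seven classes to an aligned read."""
    junctions = aln.junctions
    novelty = [label_junction_novelty(j, db, genome) for j in junctions]
    rec = AnnotationRecord(
        read_id=aln.read_id, tclass="Intergenic", junctions=junctions,
        junction_novelty=novelty, ccs_count=ccs_count,
    )

    sides = _fusion_check(aln, db, fusion_min_segment)
    if sides is not None:
        rec.tclass = "Fusion"
        rec.fusion_sides = sides
        rec.genes = [s.gene_id for s in sides]
        return rec

    match = best_match(aln, db, theta)
    overlapping_genes: set[str] = set()
    for seg in aln.segments:
        s, e = seg.span
        overlapping_genes.update(db.overlapping_genes(seg.chrom, s, e))

    if match is None:
        if not overlapping_genes:
            rec.tclass = "Intergenic"
            return rec
        rec.genes = sorted(overlapping_genes)
        if aln.n_exons == 1:
            rec.tclass = "Genic"
        else:
            rec.tclass = "NIC" if all(k or _known_sites(j, db) for (k, _), j in
                                      zip(novelty, junctions)) else "NNC"
        return rec

    iso, ms = match
    rec.best_match = iso.isoform_id
    rec.match_score = ms
    rec.genes = [iso.gene_id]

    seg = aln.segments[0]
    if aln.n_exons == 1:
        rec.tclass = _classify_monoexonic(seg, db, overlapping_genes, fsm_end_window, rec)
        return rec

    read_chain = [j.key for j in junctions]
    iso_chain = [j.key for j in iso.junctions]
    retention = _has_intron_retention(aln, iso)
    if _is_subchain(read_chain, iso_chain):
        if read_chain == iso_chain and not retention:
            rs, re_ = seg.span
            if abs(rs - iso.span[0]) <= fsm_end_window and abs(re_ - iso.span[1]) <= fsm_end_window:
                rec.tclass = "FSM"
                return rec
        rec.tclass = "NIC" if retention else "ISM"
        return rec
    if all(k or _known_sites(j, db) for (k, _), j in zip(novelty, junctions)):
        rec.tclass = "NIC"
    else:
        rec.tclass = "NNC"
    return rec


def _known_sites(j: Junction, db: IsoformDB) -> bool:
    """A novel junction still counts toward NIC when both its donor and
    acceptor are annotated splice sites."""
    return (j.chrom, j.donor) in db.donor_sites and (j.chrom, j.acceptor) in db.acceptor_sites


def _classify_monoexonic(
    seg, db: IsoformDB, genes: set[str], end_window: int, rec: AnnotationRecord
) -> str:
    rs, re_ = seg.span
    for iso in db.overlapping_isoforms(seg.chrom, rs, re_):
        if len(iso.exons) == 1:
            s, e = iso.span
            if abs(rs - s) <= end_window and abs(re_ - e) <= end_window:
                rec.best_match = iso.isoform_id
                rec.genes = [iso.gene_id]
                return "FSM"
    for iso in db.overlapping_isoforms(seg.chrom, rs, re_):
        if len(iso.exons) > 1:
            for es, ee in iso.exons:
                if abs(rs - es) <= end_window and abs(re_ - ee) <= end_window:
                    rec.best_match = iso.isoform_id
                    rec.genes = [iso.gene_id]
                    return "ISM"
    return "Genic" if genes else "Intergenic"


def annotate_all(
    alignments: Iterable[SplicedAlignment],
    db: IsoformDB,
    genome: Optional[GenomeRef] = None,
    ccs_counts: Optional[dict[str, int]] = None,
    **kwargs,
) -> list[AnnotationRecord]:
    out = []
    for aln in alignments:
        if not aln.is_mapped:
            continue
        ccs = (ccs_counts or {}).get(aln.read_id, 1)
        out.append(classify(aln, db, genome, ccs_count=ccs, **kwargs))
    return out


def write_annotation_tsv(records: Iterable[AnnotationRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\tbest_match\tgenes\tn_junctions\tn_novel_junctions\tccs_count\n")
        for r in records:
            novel = sum(1 for known, _ in r.junction_novelty if not known)
            fh.write(
                f"{r.read_id}\t{r.tclass}\t{r.best_match or '.'}\t"
                f"{','.join(r.genes) or '.'}\t{len(r.junctions)}\t{novel}\t{r.ccs_count}\n"
            )
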