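"""Synthetic data generation and the evaluation protocols.

The generator builds a small multi-gene genome whose introns carry realistic
splice-site signal: a deterministic GT..AG core with an extended donor
consensus (GTRAGT-like) and an acceptor polypyrimidine tract, as spliceosomal
introns do.  A configurable fraction of junctions is planted with short
sequence repeats across the boundary so that junction wobble (several
base-equivalent placements) actually occurs, which is what the splice-site
correction stage exists to resolve.

On top of the world sit the two evaluation protocols: annotation deletion
(remove X% of genes, measure sensitivity/precision of junction rediscovery)
and fusion simulation (concatenated partner-gene transcripts with random
breakpoints, SNPs/indels and 1..5 supporting reads each), plus RNA-seq-style
spliced short reads for junction support scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .hybrid_align import LongRead, slice_windows
from .refio import GenomeRef, Isoform, IsoformDB, Junction, revcomp

BASES = "ACGT"

# cigar op codes
M, I, D, N, S = 0, 1, 2, 3, 4


@dataclass
class WorldConfig:
    n_genes: int = 50
    n_chroms: int = 2
    exons_per_gene: tuple[int, int] = (2, 12)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 400)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    monoexonic_gene_frac: float = 0.08
    wobble_frac: float = 0.35
    wobble_len: tuple[int, int] = (2, 4)
    intergenic: tuple[int, int] = (300, 800)
    chrom_pad: int = 200


@dataclass
class SyntheticWorld:
    genome: GenomeRef
    db: IsoformDB
    config: WorldConfig
    seed: int

    @property
    def sam_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": l} for n, l in self.genome.lengths.items()],
        })


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _donor_consensus(rng: np.random.Generator) -> str:
    """First six intron bases, GT fixed, GTRAGT-like extended consensus."""
    return "GT" + _choice(rng, {"A": 0.7, "G": 0.3}) \
        + _choice(rng, {"A": 0.85, "C": 0.05, "G": 0.05, "T": 0.05}) \
        + _choice(rng, {"G": 0.85, "A": 0.05, "C": 0.05, "T": 0.05}) \
        + _choice(rng, {"T": 0.8, "A": 0.1, "C": 0.05, "G": 0.05})


def _acceptor_consensus(rng: np.random.Generator) -> str:
    """Last fourteen intron bases: polypyrimidine tract then (C)AG, AG fixed."""
    tract = "".join(
        _choice(rng, {"C": 0.44, "T": 0.44, "A": 0.06, "G": 0.06}) for _ in range(10)
    )
    return tract + _rand_seq(rng, 1) + _choice(rng, {"C": 0.8, "T": 0.2}) + "AG"


def _make_intron(rng: np.random.Generator, length: int) -> str:
    middle = _rand_seq(rng, length - 20)
    return _donor_consensus(rng) + middle + _acceptor_consensus(rng)


def make_world(config: WorldConfig = WorldConfig(), seed: int = 0) -> SyntheticWorld:
    """Deterministic synthetic genome + annotation under one seed."""
    rng = np.random.default_rng(seed)
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [_rand_seq(rng, config.chrom_pad)] for i in range(config.n_chroms)
    }
    chrom_len: dict[str, int] = {c: config.chrom_pad for c in chrom_parts}
    isoforms: list[Isoform] = []
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:03d}"
        chrom = f"chr{g % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        mono = rng.random() < config.monoexonic_gene_frac
        if mono:
            exon_lens = [int(rng.integers(300, 1500))]
            intron_lens: list[int] = []
        else:
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = [int(rng.integers(*config.exon_len)) for _ in range(n_ex)]
            intron_lens = [int(rng.integers(*config.intron_len)) for _ in range(n_ex - 1)]
        # transcription-oriented gene sequence with recorded exon intervals
        parts: list[str] = []
        exons_local: list[tuple[int, int]] = []
        pos = 0
        for i, el in enumerate(exon_lens):
            parts.append(_rand_seq(rng, el))
            exons_local.append((pos, pos + el))
            pos += el
            if i < len(intron_lens):
                parts.append(_make_intron(rng, intron_lens[i]))
                pos += intron_lens[i]
        seq = list("".join(parts))
        # plant wobble repeats across a fraction of junctions
        for i in range(len(exon_lens) - 1):
            if rng.random() >= config.wobble_frac:
                continue
            k = int(rng.integers(config.wobble_len[0], config.wobble_len[1] + 1))
            d = exons_local[i][1]                 # first intron base
            a = exons_local[i + 1][0]             # first exon base after intron
            if rng.random() < 0.5:
                if exon_lens[i + 1] > k + 2:      # rightward wobble: exon head repeats intron head
                    seq[a:a + k] = seq[d:d + k]
            else:
                if exon_lens[i] > k + 2:          # leftward wobble: exon tail repeats intron tail
                    seq[d - k:d] = seq[a - k:a]
        gene_seq = "".join(seq)
        glen = len(gene_seq)
        if strand == "-":
            gene_seq = revcomp(gene_seq)
            exons_local = [(glen - e, glen - s) for s, e in exons_local][::-1]
        offset = chrom_len[chrom]
        chrom_parts[chrom].append(gene_seq)
        chrom_len[chrom] += glen
        gap = int(rng.integers(*config.intergenic))
        chrom_parts[chrom].append(_rand_seq(rng, gap))
        chrom_len[chrom] += gap
        exons = tuple((offset + s, offset + e) for s, e in exons_local)
        # isoform variants share junction subsets of the full exon chain
        n_iso = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        variants: list[tuple[tuple[int, int], ...]] = [exons]
        if not mono and len(exons) >= 3:
            for _ in range(n_iso - 1):
                if len(exons) >= 4 and rng.random() < 0.5:
                    skip = int(rng.integers(1, len(exons) - 1))
                    var = exons[:skip] + exons[skip + 1:]
                else:
                    var = exons[1:] if strand == "+" else exons[:-1]
                if var not in variants:
                    variants.append(var)
        for k, var in enumerate(variants):
            isoforms.append(Isoform(f"{gene_id}.t{k + 1}", gene_id, chrom, strand, var))
    genome = GenomeRef({c: "".join(p) for c, p in chrom_parts.items()})
    return SyntheticWorld(genome, IsoformDB(isoforms), config, seed)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class TruthRecord:
    read_id: str
    isoform_id: str
    gene_id: str
    truth_class: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def junction_keys(self) -> set[tuple[str, int, int]]:
        return {
            (self.chrom, e1, s2)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        }


def _simulate_over_exons(
    genome: GenomeRef,
    chrom: str,
    exons: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
):
    """Walk an exon chain in genomic order emitting a corrupted read.

    Returns (forward-oriented sequence, per-base reference positions with None
    for inserted bases, cigartuples in reference order, reference start)."""
    seq: list[str] = []
    pairs: list[Optional[int]] = []
    cigar: list[list[int]] = []

    def add_op(op: int, ln: int = 1):
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += ln
        else:
            cigar.append([op, ln])

    first_pos = exons[0][0]
    last_pos = exons[-1][1] - 1
    for ei, (s, e) in enumerate(exons):
        if ei > 0:
            add_op(N, s - exons[ei - 1][1])
        for r in range(s, e):
            edge = r in (first_pos, last_pos)
            if not edge and del_rate and rng.random() < del_rate:
                add_op(D)
                continue
            base = genome.sequences[chrom][r]
            if sub_rate and rng.random() < sub_rate:
                base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4] \
                    if base in BASES else "A"
            seq.append(base)
            pairs.append(r)
            add_op(M)
            if not edge and ins_rate and rng.random() < ins_rate:
                k = int(rng.integers(1, 4))
                seq.extend(_rand_seq(rng, k))
                pairs.extend([None] * k)
                add_op(I, k)
    return "".join(seq), pairs, [tuple(c) for c in cigar], exons[0][0]


def _make_record(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    ref_start: int,
    cigar: Sequence[tuple[int, int]],
    fwd_seq: str,
    is_reverse: bool,
    supplementary: bool = False,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header=header)
    rec.query_name = name
    rec.query_sequence = fwd_seq
    rec.reference_id = header.get_tid(chrom)
    rec.reference_start = ref_start
    rec.mapping_quality = 60
    rec.cigartuples = list(cigar)
    rec.flag = (16 if is_reverse else 0) | (2048 if supplementary else 0)
    return rec


def _cigar_from_pairs(pairs: Sequence[Optional[int]], min_intron: int = 20):
    """Rebuild (ref_start, cigartuples) for a slice of per-base ref positions;
    unaligned edges become soft clips, internal gaps D or N by size."""
    idx = [i for i, p in enumerate(pairs) if p is not None]
    if not idx:
        return None, None
    lead, tail = idx[0], len(pairs) - 1 - idx[-1]
    cigar: list[list[int]] = []

    def add_op(op: int, ln: int = 1):
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += ln
        else:
            cigar.append([op, ln])

    if lead:
        add_op(S, lead)
    prev = None
    for p in pairs[idx[0]:idx[-1] + 1]:
        if p is None:
            add_op(I)
            continue
        if prev is not None and p > prev + 1:
            gap = p - prev - 1
            add_op(N if gap >= min_intron else D, gap)
        add_op(M)
        prev = p
    if tail:
        add_op(S, tail)
    return pairs[idx[0]], [tuple(c) for c in cigar]


@dataclass
class SimulatedReads:
    reads: list[LongRead]
    truths: dict[str, TruthRecord]
    long_records: list[pysam.AlignedSegment]
    short_records: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader


def simulate_reads(
    world: SyntheticWorld,
    n_reads: int = 200,
    seed: int = 0,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    truncate_frac: float = 0.0,
    window: int = 250,
    step: int = 100,
    ccs_range: tuple[int, int] = (1, 6),
    expression: Optional[dict[str, int]] = None,
    emit_windows: bool = True,
) -> SimulatedReads:
    """Full-length (and optionally 5'-truncated) reads with truth alignments.

    Truth SAM records for the long reads and their sliding-window slices stand
    in for an external aligner's output, so the assembly stage can be driven
    without invoking one."""
    rng = np.random.default_rng(seed)
    header = world.sam_header
    iso_ids = sorted(world.db.isoforms)
    if expression is not None:
        draw = [i for i, c in sorted(expression.items()) for _ in range(c)]
    else:
        draw = [iso_ids[int(k)] for k in rng.integers(0, len(iso_ids), size=n_reads)]
    out = SimulatedReads([], {}, [], [], header)
    for ridx, iso_id in enumerate(draw):
        iso = world.db.isoforms[iso_id]
        read_id = f"read{ridx:05d}"
        exons = list(iso.exons)
        truth_class = "FSM"
        if truncate_frac and len(exons) >= 3 and rng.random() < truncate_frac:
            # 5'-shortened, junction-preserving truncation
            k = int(rng.integers(1, len(exons) - 1))
            if iso.strand == "+":
                exons = exons[k:]
                trim = int(rng.integers(0, (exons[0][1] - exons[0][0]) // 2))
                exons[0] = (exons[0][0] + trim, exons[0][1])
            else:
                exons = exons[:-k] if k else exons
                trim = int(rng.integers(0, (exons[-1][1] - exons[-1][0]) // 2))
                exons[-1] = (exons[-1][0], exons[-1][1] - trim)
            truth_class = "ISM"
        fwd_seq, pairs, cigar, ref_start = _simulate_over_exons(
            world.genome, iso.chrom, exons, rng, sub_rate, ins_rate, del_rate
        )
        is_rev = iso.strand == "-"
        read_seq = revcomp(fwd_seq) if is_rev else fwd_seq
        ccs = int(rng.integers(ccs_range[0], ccs_range[1] + 1))
        read = LongRead(read_id, read_seq, ccs)
        out.reads.append(read)
        out.truths[read_id] = TruthRecord(
            read_id, iso_id, iso.gene_id, truth_class, iso.chrom, iso.strand, tuple(exons)
        )
        out.long_records.append(
            _make_record(header, read_id, iso.chrom, ref_start, cigar, fwd_seq, is_rev)
        )
        if emit_windows:
            L = len(read_seq)
            for off, wlen in slice_windows(read, window, step).windows:
                if is_rev:
                    lo, hi = L - off - wlen, L - off
                else:
                    lo, hi = off, off + wlen
                wstart, wcigar = _cigar_from_pairs(pairs[lo:hi])
                if wstart is None:
                    continue
                out.short_records.append(_make_record(
                    header, f"{read_id}|{off}", iso.chrom, wstart, wcigar,
                    fwd_seq[lo:hi], is_rev,
                ))
    return out


def write_sam(records: Iterable[pysam.AlignedSegment], header: pysam.AlignmentHeader,
              path: str) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def write_reads_fasta(reads: Iterable[LongRead], path: str) -> None:
    """Polished-transcript FASTA; CCS support encoded as ``ccs=N`` in the header."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} ccs={r.ccs_count}\n{r.sequence}\n")


def load_reads_fasta(path: str) -> list[LongRead]:
    reads = []
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            ccs = 1
            for tok in (entry.comment or "").split():
                if tok.startswith("ccs="):
                    ccs = int(tok[4:])
            reads.append(LongRead(entry.name, entry.sequence.upper(), ccs))
    return reads


def simulate_rnaseq(
    world: SyntheticWorld,
    n_reads: int = 2000,
    read_len: int = 100,
    seed: int = 0,
) -> list[pysam.AlignedSegment]:
    """Spliced RNA-seq-like short reads sampled uniformly from isoforms."""
    rng = np.random.default_rng(seed)
    header = world.sam_header
    iso_ids = sorted(world.db.isoforms)
    records = []
    for ridx in range(n_reads):
        iso = world.db.isoforms[iso_ids[int(rng.integers(0, len(iso_ids)))]]
        tlen = iso.exonic_length
        if tlen <= read_len:
            continue
        start = int(rng.integers(0, tlen - read_len))
        # map [start, start+read_len) in exon-concatenated space to the genome
        pieces = []
        offset = 0
        remaining_lo, remaining_hi = start, start + read_len
        for s, e in iso.exons:
            elen = e - s
            lo = max(remaining_lo, offset)
            hi = min(remaining_hi, offset + elen)
            if lo < hi:
                pieces.append((s + lo - offset, s + hi - offset))
            offset += elen
        cigar: list[tuple[int, int]] = []
        seq = []
        for pi, (s, e) in enumerate(pieces):
            if pi > 0:
                cigar.append((N, s - pieces[pi - 1][1]))
            cigar.append((M, e - s))
            seq.append(world.genome.fetch(iso.chrom, s, e))
        records.append(_make_record(
            header, f"rna{ridx:06d}", iso.chrom, pieces[0][0], cigar, "".join(seq), False
        ))
    return records


def junction_support(
    records: Iterable[pysam.AlignedSegment],
    junctions: Iterable[Junction | tuple[str, int, int]],
    db: Optional[IsoformDB] = None,
    min_reads: int = 2,
) -> dict[tuple[str, int, int], tuple[int, bool]]:
    """Count spliced reads whose gap exactly matches each junction.

    A junction is supported when at least ``min_reads`` reads span it or it is
    present in the reference database."""
    counts: dict[tuple[str, int, int], int] = {}
    for rec in records:
        if rec.is_unmapped or rec.cigartuples is None:
            continue
        pos = rec.reference_start
        chrom = rec.reference_name
        for op, ln in rec.cigartuples:
            if op == N:
                counts[(chrom, pos, pos + ln)] = counts.get((chrom, pos, pos + ln), 0) + 1
            if op in (M, D, N, 7, 8):
                pos += ln
    out = {}
    for j in junctions:
        key = j.key if isinstance(j, Junction) else tuple(j)
        c = counts.get(key, 0)
        supported = c >= min_reads or (db is not None and key in db.junction_set)
        out[key] = (c, supported)
    return out


def truth_alignment(truth: TruthRecord) -> "SplicedAlignment":
    """The error-free spliced alignment implied by a truth record."""
    from .hybrid_align import Segment, SplicedAlignment

    mapped = sum(e - s for s, e in truth.exons)
    seg = Segment(truth.chrom, truth.strand, list(truth.exons), 0, mapped)
    return SplicedAlignment(truth.read_id, [seg], mapped, mapped)


def corrupt_junctions(
    genome: GenomeRef,
    aln: "SplicedAlignment",
    rng: np.random.Generator,
    max_shift: int = 5,
) -> tuple["SplicedAlignment", int]:
    """Shift each junction to a random non-truth wobble-equivalent placement
    within ±max_shift where one exists (emulating aligner junction wobble).

    Returns the corrupted alignment and the number of junctions shifted."""
    import copy

    from .splice_correct import wobble_candidates

    out = copy.deepcopy(aln)
    shifted = 0
    for seg in out.segments:
        for i in range(len(seg.exons) - 1):
            j = Junction(seg.chrom, seg.exons[i][1], seg.exons[i + 1][0], seg.strand)
            cands = [
                c for c in wobble_candidates(
                    genome, j, max_shift,
                    left_bound=seg.exons[i][0], right_bound=seg.exons[i + 1][1])
                if c.start != j.start
            ]
            if not cands:
                continue
            pick = cands[int(rng.integers(0, len(cands)))]
            seg.exons[i] = (seg.exons[i][0], pick.start)
            seg.exons[i + 1] = (pick.end, seg.exons[i + 1][1])
            shifted += 1
    return out, shifted


# ---------------------------------------------------------------------------
# annotation-deletion protocol


@dataclass
class EvalCounts:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            import warnings

            warnings.warn("empty positive set: sensitivity undefined")
            return math.nan
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return math.nan
        return self.tp / (self.tp + self.fp)


def delete_annotation(
    db: IsoformDB, x_percent: float, seed: int = 0
) -> tuple[IsoformDB, set[tuple[str, int, int]], list[str]]:
    """Remove all isoforms of a random X% of genes; the removed genes'
    junctions form the positive set of the rediscovery evaluation."""
    if not 0 < x_percent < 100:
        raise ValueError("X must be strictly between 0 and 100")
    rng = np.random.default_rng(seed)
    genes = sorted(db.genes)
    k = max(1, int(round(len(genes) * x_percent / 100)))
    removed = sorted(rng.choice(len(genes), size=k, replace=False))
    removed_genes = [genes[i] for i in removed]
    keep = [g for g in genes if g not in set(removed_genes)]
    deleted_junctions: set[tuple[str, int, int]] = set()
    for g in removed_genes:
        for tid in db.genes[g]:
            for j in db.isoforms[tid].junctions:
                deleted_junctions.add(j.key)
    return db.subset(keep), deleted_junctions, removed_genes


def sensitivity_precision(
    reported: Iterable[tuple[str, int, int]],
    positives: Iterable[tuple[str, int, int]],
) -> EvalCounts:
    rep, pos = set(reported), set(positives)
    tp = len(rep & pos)
    return EvalCounts(tp=tp, fp=len(rep - pos), fn=len(pos - rep))


# ---------------------------------------------------------------------------
# fusion simulation


@dataclass
class FusionSimConfig:
    n_datasets: int = 10
    n_fusions: int = 300
    n_background: int = 2000  # paper-scale runs use ~20,000
    support_range: tuple[int, int] = (1, 5)
    ccs_range: tuple[int, int] = (1, 5)
    sub_rate: float = 0.005
    ins_rate: float = 0.001
    del_rate: float = 0.001
    min_part: int = 50


@dataclass
class FusionTruth:
    fusion_id: str
    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    chrom3: str
    breakpoint3: int
    n_supporting: int
    read_ids: list[str]


@dataclass
class FusionDataset:
    reads: list[LongRead]
    truths: list[FusionTruth]
    long_records: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader


def _prefix_exons(exons: Sequence[tuple[int, int]], tlen: int) -> list[tuple[int, int]]:
    out = []
    left = tlen
    for s, e in exons:
        take = min(e - s, left)
        out.append((s, s + take))
        left -= take
        if left == 0:
            break
    return out


def _suffix_exons(exons: Sequence[tuple[int, int]], tlen: int) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    left = tlen
    for s, e in reversed(exons):
        take = min(e - s, left)
        out.insert(0, (e - take, e))
        left -= take
        if left == 0:
            break
    return out


def simulate_fusions(
    world: SyntheticWorld,
    config: FusionSimConfig = FusionSimConfig(),
    seed: int = 0,
) -> list[FusionDataset]:
    """Fusion datasets: concatenated partner transcripts at random breakpoints
    plus background non-fusion transcripts (genes used in fusions excluded)."""
    eligible = [
        gid for gid in sorted(world.db.genes)
        if world.db.isoforms[world.db.genes[gid][0]].strand == "+"
        and world.db.isoforms[world.db.genes[gid][0]].exonic_length >= 3 * config.min_part
    ]
    if len(eligible) < 2:
        raise ValueError("world needs at least two eligible fusion partner genes")
    datasets = []
    header = world.sam_header
    for d in range(config.n_datasets):
        rng = np.random.default_rng([seed, d])
        reads: list[LongRead] = []
        truths: list[FusionTruth] = []
        records: list[pysam.AlignedSegment] = []
        fusion_genes: set[str] = set()
        for f in range(config.n_fusions):
            ga, gb = (eligible[i] for i in rng.choice(len(eligible), size=2, replace=False))
            iso_a = world.db.isoforms[world.db.genes[ga][0]]
            iso_b = world.db.isoforms[world.db.genes[gb][0]]
            ua = int(rng.integers(config.min_part, iso_a.exonic_length - config.min_part))
            ub = int(rng.integers(config.min_part, iso_b.exonic_length - config.min_part))
            part_a = _prefix_exons(iso_a.exons, ua)
            part_b = _suffix_exons(iso_b.exons, ub)
            n_support = int(rng.integers(config.support_range[0], config.support_range[1] + 1))
            fusion_id = f"fusion_d{d}_{f:04d}"
            read_ids = []
            for s in range(n_support):
                rid = f"{fusion_id}_r{s}"
                seq_a, _, cigar_a, start_a = _simulate_over_exons(
                    world.genome, iso_a.chrom, part_a, rng,
                    config.sub_rate, config.ins_rate, config.del_rate)
                seq_b, _, cigar_b, start_b = _simulate_over_exons(
                    world.genome, iso_b.chrom, part_b, rng,
                    config.sub_rate, config.ins_rate, config.del_rate)
                full = seq_a + seq_b
                ccs = int(rng.integers(config.ccs_range[0], config.ccs_range[1] + 1))
                reads.append(LongRead(rid, full, ccs))
                records.append(_make_record(
                    header, rid, iso_a.chrom, start_a,
                    list(cigar_a) + [(S, len(seq_b))], full, False))
                records.append(_make_record(
                    header, rid, iso_b.chrom, start_b,
                    [(S, len(seq_a))] + list(cigar_b), full, False,
                    supplementary=True))
                read_ids.append(rid)
            truths.append(FusionTruth(
                fusion_id, ga, gb, iso_a.chrom, part_a[-1][1],
                iso_b.chrom, part_b[0][0], n_support, read_ids))
            fusion_genes.update((ga, gb))
        background_pool = [
            tid for tid in sorted(world.db.isoforms)
            if world.db.isoforms[tid].gene_id not in fusion_genes
        ]
        for b in range(config.n_background):
            iso = world.db.isoforms[background_pool[int(rng.integers(0, len(background_pool)))]]
            rid = f"bg_d{d}_{b:05d}"
            fwd, _, cigar, start = _simulate_over_exons(
                world.genome, iso.chrom, iso.exons, rng,
                config.sub_rate, config.ins_rate, config.del_rate)
            is_rev = iso.strand == "-"
            reads.append(LongRead(rid, revcomp(fwd) if is_rev else fwd,
                                  int(rng.integers(config.ccs_range[0], config.ccs_range[1] + 1))))
            records.append(_make_record(header, rid, iso.chrom, start, cigar, fwd, is_rev))
        datasets.append(FusionDataset(reads, truths, records, header))
    return datasets


def write_fusion_truth_tsv(truths: Sequence[FusionTruth], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("fusion_id\tgene5\tgene3\tbreakpoint5\tbreakpoint3\tn_supporting\n")
        for t in truths:
            fh.write(f"{t.fusion_id}\t{t.gene5}\t{t.gene3}\t{t.chrom5}:{t.breakpoint5}\t"
                     f"{t.chrom3}:{t.breakpoint3}\t{t.n_supporting}\n")
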