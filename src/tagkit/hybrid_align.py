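"""Hybrid long/short-read alignment assembly.

A polished long read carries one spliced long-read mapping plus the mappings of
its sliding-window slices re-aligned as short reads.  Each read base therefore
has a set of candidate genome positions; bases where all mappings agree are
uniquely mapped, the rest are resolved by a scored local-alignment combination
search (greedy run enumeration followed by subset selection, penalising the
number of chosen runs, their pairwise read overlap and their distance to the
uniquely mapped anchors flanking the block).

The final per-base assignment is compressed into exon blocks; gaps of at least
``min_intron`` between consecutive blocks on one chromosome become splice
junctions, smaller gaps are absorbed as deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import pysam

from .refio import Junction

DEFAULT_WINDOW = 250
DEFAULT_STEP = 100
DEFAULT_MU = (2.0, 2.0, 1.0, 1.0)
DEFAULT_XCHROM_DIST = 1000.0
DEFAULT_EXHAUSTIVE_BOUND = 12
DEFAULT_MIN_INTRON = 20
MULTI_BLOCK_MAX_SHORT = 10  # multiply-mapped blocks up to this length take the long-read mapping


@dataclass
class LongRead:
    read_id: str
    sequence: str
    ccs_count: int = 1

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"empty read {self.read_id}")
        if self.ccs_count < 1:
            raise ValueError("ccs_count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class WindowSet:
    """Sliding windows R_1..R_n of length <= h at step t; the last window is
    anchored at the read end so the whole read is covered."""

    h: int
    t: int
    windows: list[tuple[int, int]]  # (read offset, window length)

    @property
    def n(self) -> int:
        return len(self.windows)


def slice_windows(read: LongRead, h: int = DEFAULT_WINDOW, t: int = DEFAULT_STEP) -> WindowSet:
    if h <= 0 or t <= 0:
        raise ValueError("window length and step must be positive")
    if t > h:
        raise ValueError("step must not exceed window length")
    L = read.length
    if L <= h:
        return WindowSet(h, t, [(0, L)])
    n = math.ceil((L - h + t) / t)
    offsets = [i * t for i in range(n - 1)] + [L - h]
    return WindowSet(h, t, [(o, h) for o in offsets])


def write_window_fasta(read: LongRead, windows: WindowSet, path: str) -> None:
    """Window slices for an external spliced short-read aligner; the read name
    encodes the read offset as ``readID|offset``."""
    with open(path, "w") as fh:
        for offset, length in windows.windows:
            fh.write(f">{read.read_id}|{offset}\n{read.sequence[offset:offset + length]}\n")


@dataclass
class PositionMatrix:
    """Per-read-base candidate genome positions, sorted by (chromosome, coord).

    ``candidates[i]`` is a tuple of ``(chrom, pos)``; its weight is ``1/n_i``.
    ``long_pos[i]`` is the long-read mapping's own candidate (or None)."""

    read_id: str
    length: int
    candidates: list[tuple[tuple[str, int], ...]]
    long_pos: list[Optional[tuple[str, int]]]
    flipped: bool  # True when the primary long-read mapping is reverse-strand
    strand: str

    def n(self, i: int) -> int:
        return len(self.candidates[i])

    def weight(self, i: int) -> float:
        n = len(self.candidates[i])
        return 1.0 / n if n else 0.0

    def is_unmapped(self, i: int) -> bool:
        return not self.candidates[i]


def _aligned_read_pairs(rec: pysam.AlignedSegment, offset: int, wlen: int, L: int,
                        flipped: bool) -> Iterable[tuple[int, int]]:
    """Yield (working read position, genome position) for a SAM record whose
    query is the read slice ``[offset, offset+wlen)`` of the original read.

    Working coordinates equal original read coordinates, reversed end-to-end
    when the primary long-read mapping is reverse-strand so that genome
    positions increase along the working read."""
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        orig = offset + (qpos if not rec.is_reverse else wlen - 1 - qpos)
        if orig >= L or orig < 0:
            raise ValueError(
                f"alignment of {rec.query_name} addresses read position {orig} beyond length {L}"
            )
        yield (L - 1 - orig if flipped else orig), rpos


def build_position_matrix(
    long_mappings: Sequence[pysam.AlignedSegment],
    short_mappings: Sequence[pysam.AlignedSegment],
    read: LongRead,
    include_secondary: bool = True,
) -> PositionMatrix:
    """Union of long-read and window short-read candidate positions per base.

    Short-read query names must carry the window offset as ``readID|offset``.
    """
    L = read.length
    primaries = [r for r in long_mappings if not r.is_secondary and not r.is_supplementary]
    primary = primaries[0] if primaries else (long_mappings[0] if long_mappings else None)
    flipped = bool(primary is not None and primary.is_reverse)
    cand: list[set[tuple[str, int]]] = [set() for _ in range(L)]
    long_pos: list[Optional[tuple[str, int]]] = [None] * L
    for rec in long_mappings:
        if rec.is_unmapped:
            continue
        if rec.is_secondary and not include_secondary:
            continue
        chrom = rec.reference_name
        for wpos, rpos in _aligned_read_pairs(rec, 0, L, L, flipped):
            cand[wpos].add((chrom, rpos))
            if not rec.is_secondary and long_pos[wpos] is None:
                long_pos[wpos] = (chrom, rpos)
    for rec in short_mappings:
        if rec.is_unmapped:
            continue
        if rec.is_secondary and not include_secondary:
            continue
        name = rec.query_name
        if "|" not in name:
            raise ValueError(f"short-read name {name!r} lacks |offset suffix")
        rid, off_s = name.rsplit("|", 1)
        if rid != read.read_id:
            continue
        offset = int(off_s)
        wlen = rec.query_length or rec.infer_query_length()
        chrom = rec.reference_name
        for wpos, rpos in _aligned_read_pairs(rec, offset, wlen, L, flipped):
            cand[wpos].add((chrom, rpos))
    candidates = [tuple(sorted(c)) for c in cand]
    return PositionMatrix(
        read_id=read.read_id,
        length=L,
        candidates=candidates,
        long_pos=long_pos,
        flipped=flipped,
        strand="-" if flipped else "+",
    )


@dataclass
class Block:
    """Maximal run of uniquely- or multiply-mapped read positions, half-open."""

    start: int
    end: int
    kind: str  # "unique" | "multi"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def needs_algorithm(self) -> bool:
        return self.kind == "multi" and self.length > MULTI_BLOCK_MAX_SHORT


def partition_blocks(matrix: PositionMatrix) -> list[Block]:
    """Partition the read into alternating uniquely/multiply mapped blocks.

    A base is uniquely mapped iff it has exactly one candidate position;
    unmapped bases (no candidates) belong to multiply-mapped blocks."""
    blocks: list[Block] = []
    i = 0
    L = matrix.length
    while i < L:
        kind = "unique" if matrix.n(i) == 1 else "multi"
        j = i + 1
        while j < L and ("unique" if matrix.n(j) == 1 else "multi") == kind:
            j += 1
        blocks.append(Block(i, j, kind))
        i = j
    return blocks


@dataclass
class LocalAlignment:
    """A maximal colinear run of candidate positions inside one block."""

    tau: int
    read_start: int
    read_end: int  # half-open
    chrom: str
    gstart: int
    quality: float

    @property
    def gend(self) -> int:
        return self.gstart + (self.read_end - self.read_start)


def enumerate_local_alignments(block: Block, matrix: PositionMatrix) -> list[LocalAlignment]:
    """Greedy maximal consecutive-run enumeration over a multiply-mapped block.

    Starting from the first candidate not yet covered, a run extends while the
    next read position offers a candidate exactly one base downstream on the
    same chromosome; every candidate ends up in some run."""
    used: set[tuple[int, tuple[str, int]]] = set()
    runs: list[LocalAlignment] = []
    tau = 1
    positions = range(block.start, block.end)
    while True:
        seed = None
        for i in positions:
            for c in matrix.candidates[i]:
                if (i, c) not in used:
                    seed = (i, c)
                    break
            if seed:
                break
        if seed is None:
            break
        i0, (chrom, pos0) = seed
        members = [(i0, (chrom, pos0))]
        k, pos = i0, pos0
        while k + 1 < block.end:
            nxt = (chrom, pos + 1)
            if nxt in matrix.candidates[k + 1]:
                members.append((k + 1, nxt))
                k += 1
                pos += 1
            else:
                break
        q = 0.0
        for i, c in members:
            used.add((i, c))
            q += matrix.weight(i)
        runs.append(LocalAlignment(tau, i0, k + 1, chrom, pos0, q))
        tau += 1
    return runs


@dataclass
class CombinationScore:
    """A scored choice of local alignments for one multiply-mapped block."""

    chosen: tuple[LocalAlignment, ...]
    total_quality: float
    overlap: float
    k: int
    d1: float
    d2: float
    score: float


def _read_overlap(a: LocalAlignment, b: LocalAlignment) -> int:
    return max(0, min(a.read_end, b.read_end) - max(a.read_start, b.read_start))


def _anchor_distance(anchor: Optional[tuple[str, int]], run: LocalAlignment,
                     upstream: bool, xchrom: float) -> float:
    """Penalty distance between a flanking uniquely-mapped anchor and the run
    nearest to it; log10-compressed genomic gap on the same chromosome when the
    placement is correctly ordered, the large constant otherwise."""
    if anchor is None:
        return 0.0
    chrom, pos = anchor
    if chrom != run.chrom:
        return xchrom
    gap = (run.gstart - (pos + 1)) if upstream else (pos - run.gend)
    if gap < 0:
        return xchrom
    return math.log10(1 + gap)


def _score_combination(
    subset: Sequence[LocalAlignment],
    mu: Sequence[float],
    upstream_anchor: Optional[tuple[str, int]],
    downstream_anchor: Optional[tuple[str, int]],
    xchrom: float,
) -> CombinationScore:
    ordered = sorted(subset, key=lambda r: (r.read_start, r.read_end, r.chrom, r.gstart))
    total_q = sum(r.quality for r in ordered)
    overlap = float(sum(_read_overlap(a, b) for a, b in combinations(ordered, 2)))
    k = len(ordered)
    d1 = _anchor_distance(upstream_anchor, ordered[0], True, xchrom)
    d2 = _anchor_distance(downstream_anchor, ordered[-1], False, xchrom)
    score = total_q - mu[0] * overlap - mu[1] * k - mu[2] * d1 - mu[3] * d2
    return CombinationScore(tuple(ordered), total_q, overlap, k, d1, d2, score)


def select_combination(
    alignments: Sequence[LocalAlignment],
    upstream_anchor: Optional[tuple[str, int]] = None,
    downstream_anchor: Optional[tuple[str, int]] = None,
    mu: Sequence[float] = DEFAULT_MU,
    xchrom_dist: float = DEFAULT_XCHROM_DIST,
    exhaustive_bound: int = DEFAULT_EXHAUSTIVE_BOUND,
) -> CombinationScore:
    """Maximise sum(Q) - mu1*O - mu2*k - mu3*D1 - mu4*D2 over combinations.

    Exhaustive over all non-empty subsets up to ``exhaustive_bound``
    alignments; beyond that, a DP over read-sorted alignments charging overlap
    against the previously chosen alignment.  Ties break toward fewer
    alignments, then the leftmost genome start."""
    if not alignments:
        raise ValueError("no local alignments to combine")
    if len(alignments) <= exhaustive_bound:
        best = None
        best_key = None
        for r in range(1, len(alignments) + 1):
            for subset in combinations(alignments, r):
                cs = _score_combination(subset, mu, upstream_anchor, downstream_anchor, xchrom_dist)
                key = (cs.score, -cs.k, -cs.chosen[0].gstart)
                if best_key is None or key > best_key:
                    best, best_key = cs, key
        return best
    order = sorted(alignments, key=lambda r: (r.read_start, r.read_end, r.gstart))
    n = len(order)
    # dp[i]: best partial score of a chain ending at i, D2 not yet charged
    dp = [0.0] * n
    back: list[Optional[int]] = [None] * n
    for i, run in enumerate(order):
        d1 = _anchor_distance(upstream_anchor, run, True, xchrom_dist)
        dp[i] = run.quality - mu[1] - mu[2] * d1
        for j in range(i):
            cand = dp[j] + run.quality - mu[1] - mu[0] * _read_overlap(order[j], run)
            if cand > dp[i]:
                dp[i], back[i] = cand, j
    best_i = max(
        range(n),
        key=lambda i: dp[i] - mu[3] * _anchor_distance(downstream_anchor, order[i], False, xchrom_dist),
    )
    chain = []
    cur: Optional[int] = best_i
    while cur is not None:
        chain.append(order[cur])
        cur = back[cur]
    chain.reverse()
    return _score_combination(chain, mu, upstream_anchor, downstream_anchor, xchrom_dist)


@dataclass
class Segment:
    """One chromosome stretch of a spliced alignment."""

    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    read_start: int
    read_end: int

    @property
    def junctions(self) -> list[Junction]:
        return [
            Junction(self.chrom, e1, s2, self.strand)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def mapped_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SplicedAlignment:
    """Assembled exon-block placement of a long read on the genome."""

    read_id: str
    segments: list[Segment]
    mapped_bases: int
    read_length: int

    @property
    def is_mapped(self) -> bool:
        return bool(self.segments)

    @property
    def junctions(self) -> list[Junction]:
        out = []
        for seg in self.segments:
            out.extend(seg.junctions)
        return out

    @property
    def n_exons(self) -> int:
        return sum(len(seg.exons) for seg in self.segments)


def _resolve_assignment(
    matrix: PositionMatrix,
    blocks: Sequence[Block],
    mu: Sequence[float],
    xchrom_dist: float,
    exhaustive_bound: int,
) -> list[Optional[tuple[str, int]]]:
    assignment: list[Optional[tuple[str, int]]] = [None] * matrix.length

    def downstream_anchor(after: int) -> Optional[tuple[str, int]]:
        for b in blocks:
            if b.kind == "unique" and b.start >= after:
                return matrix.candidates[b.start][0]
        return None

    for block in blocks:
        if block.kind == "unique":
            for i in range(block.start, block.end):
                assignment[i] = matrix.candidates[i][0]
        elif not block.needs_algorithm:
            for i in range(block.start, block.end):
                assignment[i] = matrix.long_pos[i]
        else:
            runs = enumerate_local_alignments(block, matrix)
            if not runs:
                continue
            up = None
            for i in range(block.start - 1, -1, -1):
                if assignment[i] is not None:
                    up = assignment[i]
                    break
            down = downstream_anchor(block.end)
            best = select_combination(runs, up, down, mu, xchrom_dist, exhaustive_bound)
            for run in best.chosen:  # leftmost run wins on read overlap
                for i in range(run.read_start, run.read_end):
                    if assignment[i] is None:
                        assignment[i] = (run.chrom, run.gstart + (i - run.read_start))
    return assignment


def _segments_from_assignment(
    assignment: Sequence[Optional[tuple[str, int]]],
    strand: str,
    min_intron: int,
) -> list[Segment]:
    # compress per-base assignment into strictly colinear runs
    runs: list[tuple[str, int, int, int, int]] = []  # chrom, gstart, gend, rstart, rend
    cur = None
    for i, a in enumerate(assignment):
        if a is None:
            if cur:
                runs.append(cur)
                cur = None
            continue
        chrom, pos = a
        if cur and cur[0] == chrom and pos == cur[2]:
            cur = (chrom, cur[1], pos + 1, cur[3], i + 1)
        else:
            if cur:
                runs.append(cur)
            cur = (chrom, pos, pos + 1, i, i + 1)
    if cur:
        runs.append(cur)
    segments: list[Segment] = []
    seg: Optional[Segment] = None
    last_end = None
    for chrom, gs, ge, rs, re_ in runs:
        if seg is not None and chrom == seg.chrom and last_end is not None and gs >= last_end:
            gap = gs - last_end
            if gap < min_intron:
                # deletion or insertion artefact: extend the current exon
                seg.exons[-1] = (seg.exons[-1][0], ge)
            else:
                seg.exons.append((gs, ge))
            seg.read_end = re_
            last_end = ge
        else:
            seg = Segment(chrom, strand, [(gs, ge)], rs, re_)
            segments.append(seg)
            last_end = ge
    return segments


def assemble_alignment(
    read: LongRead,
    long_mappings: Sequence[pysam.AlignedSegment],
    short_mappings: Sequence[pysam.AlignedSegment] = (),
    mu: Sequence[float] = DEFAULT_MU,
    xchrom_dist: float = DEFAULT_XCHROM_DIST,
    min_intron: int = DEFAULT_MIN_INTRON,
    exhaustive_bound: int = DEFAULT_EXHAUSTIVE_BOUND,
) -> SplicedAlignment:
    """Full assembly pipeline: matrix, block partition, run selection, exons."""
    mapped = [r for r in long_mappings if not r.is_unmapped]
    if not mapped:
        return SplicedAlignment(read.read_id, [], 0, read.length)
    matrix = build_position_matrix(mapped, short_mappings, read)
    blocks = partition_blocks(matrix)
    assignment = _resolve_assignment(matrix, blocks, mu, xchrom_dist, exhaustive_bound)
    segments = _segments_from_assignment(assignment, matrix.strand, min_intron)
    mapped_bases = sum(1 for a in assignment if a is not None)
    return SplicedAlignment(read.read_id, segments, mapped_bases, read.length)


def read_sam(path: str) -> dict[str, list[pysam.AlignedSegment]]:
    """Group SAM/BAM records by query name (window records by their base read id)."""
    out: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            rid = rec.query_name.rsplit("|", 1)[0] if "|" in rec.query_name else rec.query_name
            out.setdefault(rid, []).append(rec)
    return out


def write_bed12(alignments: Iterable[SplicedAlignment], path: str) -> None:
    """BED12: one line per chromosome segment, exon blocks as blockStarts/Sizes."""
    with open(path, "w") as fh:
        for aln in alignments:
            for si, seg in enumerate(aln.segments):
                s, e = seg.span
                name = aln.read_id if len(aln.segments) == 1 else f"{aln.read_id}.seg{si + 1}"
                sizes = ",".join(str(ee - ss) for ss, ee in seg.exons) + ","
                starts = ",".join(str(ss - s) for ss, ee in seg.exons) + ","
                fh.write(
                    f"{seg.chrom}\t{s}\t{e}\t{name}\t0\t{seg.strand}\t{s}\t{e}\t0\t"
                    f"{len(seg.exons)}\t{sizes}\t{starts}\n"
                )


def read_bed12(path: str) -> list[SplicedAlignment]:
    """Reload alignments written by :func:`write_bed12`; fusion segments are
    re-grouped by the ``.segN`` name suffix."""
    by_read: dict[str, list[tuple[int, Segment]]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            if ".seg" in name:
                rid, seg_no = name.rsplit(".seg", 1)
                idx = int(seg_no)
            else:
                rid, idx = name, 1
            by_read.setdefault(rid, []).append((idx, Segment(chrom, strand, exons, 0, 0)))
    out = []
    for rid in sorted(by_read):
        segs = [s for _, s in sorted(by_read[rid], key=lambda t: t[0])]
        rpos = 0
        for seg in segs:  # reconstruct read intervals from block sizes
            seg.read_start = rpos
            rpos += seg.mapped_length
            seg.read_end = rpos
        out.append(SplicedAlignment(rid, segs, rpos, rpos))
    return out


def write_junction_file(alignments: Iterable[SplicedAlignment], path: str) -> int:
    """Per-read junction report, one line per (read, junction); junctions seen
    in several reads appear once per read.  Returns the line count."""
    n = 0
    with open(path, "w") as fh:
        for aln in alignments:
            for j in aln.junctions:
                fh.write(f"{aln.read_id}\t{j.chrom}\t{j.strand}\t{j.start}\t{j.end}\n")
                n += 1
    return n
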