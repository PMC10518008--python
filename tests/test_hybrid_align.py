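import math
from itertools import combinations

import numpy as np
import pytest

from tagkit.hybrid_align import (Block, LocalAlignment, LongRead, PositionMatrix,
                                 assemble_alignment, build_position_matrix,
                                 enumerate_local_alignments, partition_blocks,
                                 read_bed12, select_combination, slice_windows,
                                 write_bed12, write_junction_file)


def matrix_from_candidates(cands, long_pos=None):
    return PositionMatrix(
        read_id="r", length=len(cands),
        candidates=[tuple(sorted(c)) for c in cands],
        long_pos=long_pos or [None] * len(cands),
        flipped=False, strand="+",
    )


class TestSliceWindows:
    @pytest.mark.parametrize("L,h,t,n,last", [
        (1000, 250, 100, 9, (750, 250)),   # last window covers bases 751-1000
        (250, 250, 100, 1, (0, 250)),
        (300, 250, 100, 2, (50, 250)),     # second window = s51..s300
        (100, 250, 100, 1, (0, 100)),      # read shorter than the window
    ])
    def test_window_layout(self, L, h, t, n, last):
        ws = slice_windows(LongRead("r", "A" * L), h, t)
        assert ws.n == n
        assert ws.windows[-1] == last
        off, ln = ws.windows[-1]
        assert off + ln == L  # the last window always ends at the read end

    def test_formula_count(self):
        # n equals the closed form ceil((L-h+t)/t) for reads longer than h
        for L in (300, 555, 1001, 2500):
            ws = slice_windows(LongRead("r", "A" * L), 250, 100)
            assert ws.n == math.ceil((L - 250 + 100) / 100)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            slice_windows(LongRead("r", "ACGT"), 0, 1)
        with pytest.raises(ValueError):
            slice_windows(LongRead("r", "ACGT"), 10, -1)


class TestPositionMatrix:
    def test_agreeing_mappings_unique(self, sam_factory):
        read = LongRead("r1", "ACGTACGTAC")
        long_rec = sam_factory("r1", "chr1", 500, "10M", read.sequence)
        short_rec = sam_factory("r1|0", "chr1", 500, "10M", read.sequence)
        m = build_position_matrix([long_rec], [short_rec], read)
        assert m.n(0) == 1 and m.weight(0) == 1.0
        assert m.candidates[0] == (("chr1", 500),)

    def test_disagreeing_mappings_split_weight(self, sam_factory):
        read = LongRead("r1", "ACGTACGTAC")
        long_rec = sam_factory("r1", "chr1", 500, "10M", read.sequence)
        short_rec = sam_factory("r1|0", "chr1", 700, "10M", read.sequence)
        m = build_position_matrix([long_rec], [short_rec], read)
        assert m.n(0) == 2 and m.weight(0) == 0.5
        assert m.candidates[0] == (("chr1", 500), ("chr1", 700))

    def test_soft_clipped_base_unmapped(self, sam_factory):
        read = LongRead("r1", "ACGTACGTAC")
        long_rec = sam_factory("r1", "chr1", 500, "2S8M", read.sequence)
        m = build_position_matrix([long_rec], [], read)
        assert m.is_unmapped(0) and m.is_unmapped(1)
        assert m.candidates[2] == (("chr1", 500),)

    def test_out_of_range_alignment_errors(self, sam_factory):
        read = LongRead("r1", "ACGT")
        rec = sam_factory("r1|2", "chr1", 500, "10M", "ACGTACGTAC")
        with pytest.raises(ValueError, match="beyond"):
            build_position_matrix([], [rec], read)

    def test_reverse_strand_working_coordinates(self, sam_factory):
        # reverse primary: working coordinates run along the genome
        read = LongRead("r1", "ACGTACGTAC")
        rec = sam_factory("r1", "chr1", 500, "10M", "GTACGTACGT", reverse=True)
        m = build_position_matrix([rec], [], read)
        assert m.flipped and m.strand == "-"
        assert [c[0][1] for c in m.candidates] == list(range(500, 510))


class TestPartitionBlocks:
    def test_all_unique_single_block(self):
        m = matrix_from_candidates([{("chr1", i)} for i in range(20)])
        blocks = partition_blocks(m)
        assert len(blocks) == 1 and blocks[0].kind == "unique"

    def test_short_multi_block_uses_long_read_mapping(self):
        cands = [{("chr1", i)} for i in range(10)]
        cands += [{("chr1", 10 + i), ("chr2", 50 + i)} for i in range(8)]  # 8 bp multi
        cands += [{("chr1", i)} for i in range(18, 30)]
        m = matrix_from_candidates(cands)
        blocks = partition_blocks(m)
        kinds = [(b.kind, b.length, b.needs_algorithm) for b in blocks]
        assert kinds == [("unique", 10, False), ("multi", 8, False), ("unique", 12, False)]

    def test_long_multi_block_flagged(self):
        cands = [{("chr1", i), ("chr2", i)} for i in range(30)]
        blocks = partition_blocks(matrix_from_candidates(cands))
        assert len(blocks) == 1 and blocks[0].needs_algorithm


class TestEnumerateLocalAlignments:
    def test_printed_example_runs(self):
        """b1:{100,200}, b2:{101,201}, b3:{102,300} with weight 0.5 each yields
        runs (100-102, Q=1.5), (200-201, Q=1.0), (300, Q=0.5)."""
        m = matrix_from_candidates([
            {("chr1", 100), ("chr1", 200)},
            {("chr1", 101), ("chr1", 201)},
            {("chr1", 102), ("chr1", 300)},
        ])
        runs = enumerate_local_alignments(Block(0, 3, "multi"), m)
        got = {(r.gstart, r.read_end - r.read_start, r.quality) for r in runs}
        assert got == {(100, 3, 1.5), (200, 2, 1.0), (300, 1, 0.5)}

    def test_single_consecutive_run(self):
        m = matrix_from_candidates([{("chr1", 100 + i)} for i in range(12)])
        runs = enumerate_local_alignments(Block(0, 12, "multi"), m)
        assert len(runs) == 1 and runs[0].quality == pytest.approx(12.0)

    def test_chromosomes_never_merge(self):
        m = matrix_from_candidates([{("chr1", 100)}, {("chr2", 101)}])
        runs = enumerate_local_alignments(Block(0, 2, "multi"), m)
        assert len(runs) == 2

    def test_every_candidate_covered(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cands = [
                {("chr1", int(p)) for p in rng.integers(0, 40, size=rng.integers(1, 4))}
                for _ in range(12)
            ]
            m = matrix_from_candidates(cands)
            runs = enumerate_local_alignments(Block(0, 12, "multi"), m)
            covered = set()
            for r in runs:
                for i in range(r.read_start, r.read_end):
                    covered.add((i, ("chr1", r.gstart + i - r.read_start)))
            wanted = {(i, c) for i, cs in enumerate(cands) for c in cs}
            assert wanted <= covered


def brute_force_best(runs, up, down, mu=(2, 2, 1, 1), xdist=1000.0):
    """Independent oracle: enumerate all non-empty subsets, recompute the
    score from first principles, apply the documented tie-breaks."""

    def anchor_d(anchor, run, upstream):
        if anchor is None:
            return 0.0
        chrom, pos = anchor
        if chrom != run.chrom:
            return xdist
        gap = run.gstart - pos - 1 if upstream else pos - run.gend
        return xdist if gap < 0 else math.log10(1 + gap)

    best = None
    for r in range(1, len(runs) + 1):
        for sub in combinations(runs, r):
            ordered = sorted(sub, key=lambda a: (a.read_start, a.read_end, a.chrom, a.gstart))
            q = sum(a.quality for a in ordered)
            ov = 0
            for i in range(len(ordered)):
                for j in range(i + 1, len(ordered)):
                    ov += max(0, min(ordered[i].read_end, ordered[j].read_end)
                              - max(ordered[i].read_start, ordered[j].read_start))
            score = (q - mu[0] * ov - mu[1] * len(ordered)
                     - mu[2] * anchor_d(up, ordered[0], True)
                     - mu[3] * anchor_d(down, ordered[-1], False))
            key = (score, -len(ordered), -ordered[0].gstart)
            if best is None or key > best[0]:
                best = (key, ordered)
    return best


def random_runs(rng, n):
    runs = []
    for t in range(n):
        start = int(rng.integers(0, 30))
        length = int(rng.integers(1, 10))
        runs.append(LocalAlignment(
            tau=t + 1, read_start=start, read_end=start + length,
            chrom=rng.choice(["chr1", "chr2"]),
            gstart=int(rng.integers(0, 5000)),
            quality=float(np.round(rng.uniform(0.1, 5.0), 3)),
        ))
    return runs


class TestSelectCombination:
    def test_single_alignment_chosen(self):
        run = LocalAlignment(1, 0, 5, "chr1", 100, 2.5)
        cs = select_combination([run])
        assert cs.chosen == (run,) and cs.k == 1

    def test_anchored_run_wins(self):
        """With anchors flanking the 100-102 run, that run alone is selected
        (value checked against exhaustive subset enumeration)."""
        runs = [
            LocalAlignment(1, 0, 3, "chr1", 100, 1.5),
            LocalAlignment(2, 0, 2, "chr1", 200, 1.0),
            LocalAlignment(3, 2, 3, "chr1", 300, 0.5),
        ]
        up, down = ("chr1", 99), ("chr1", 103)
        cs = select_combination(runs, up, down)
        assert cs.chosen == (runs[0],)
        key, ordered = brute_force_best(runs, up, down)
        assert cs.score == pytest.approx(key[0])
        assert list(cs.chosen) == ordered

    def test_cross_chromosome_rejected(self):
        """A distant-chromosome run of equal total quality loses through the
        1000-distance constant."""
        same = [
            LocalAlignment(1, 0, 5, "chr1", 1000, 2.0),
            LocalAlignment(2, 6, 11, "chr1", 1200, 2.0),
        ]
        distant = LocalAlignment(3, 0, 11, "chr2", 5000, 4.0)
        cs = select_combination(same + [distant], ("chr1", 990), ("chr1", 1300))
        assert all(c is not distant for c in cs.chosen)
        assert sorted(c.tau for c in cs.chosen) == [1, 2]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_combination([])

    def test_oracle_equivalence_random(self):
        """Exhaustive search equals independent brute-force enumeration."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            runs = random_runs(rng, int(rng.integers(1, 7)))
            up = ("chr1", int(rng.integers(0, 5000))) if rng.random() < 0.7 else None
            down = ("chr1", int(rng.integers(0, 5000))) if rng.random() < 0.7 else None
            cs = select_combination(runs, up, down)
            key, _ = brute_force_best(runs, up, down)
            assert cs.score == pytest.approx(key[0], abs=1e-9)


class TestAssembleAlignment:
    def test_noise_free_round_trip(self, world, sim):
        """Reads copied verbatim from isoforms with truth mappings recover all
        truth junctions (spliced-alignment completeness)."""
        long_map, short_map = {}, {}
        for r in sim.long_records:
            long_map.setdefault(r.query_name, []).append(r)
        for r in sim.short_records:
            short_map.setdefault(r.query_name.rsplit("|", 1)[0], []).append(r)
        for read in sim.reads:
            truth = sim.truths[read.read_id]
            aln = assemble_alignment(read, long_map[read.read_id],
                                     short_map.get(read.read_id, []))
            assert {j.key for j in aln.junctions} == truth.junction_keys
            assert len(aln.segments) == 1
            assert aln.segments[0].strand == truth.strand

    def test_unmapped_read_reported(self, sam_factory):
        aln = assemble_alignment(LongRead("r", "ACGT"), [])
        assert not aln.is_mapped

    def test_determinism(self, world, sim):
        read = sim.reads[0]
        recs = [r for r in sim.long_records if r.query_name == read.read_id]
        srecs = [r for r in sim.short_records
                 if r.query_name.rsplit("|", 1)[0] == read.read_id]
        a1 = assemble_alignment(read, recs, srecs)
        a2 = assemble_alignment(read, recs, srecs)
        assert [s.exons for s in a1.segments] == [s.exons for s in a2.segments]

    def test_merged_exon_rescued_by_windows(self, sam_factory):
        """A long-read mapping that runs a short middle exon into the intron
        (fragmented by the indels such misalignments carry) is overridden by
        the window mappings placing the exon at its true position."""
        # truth: exon1 1000-1100, exon2 1400-1430, exon3 1700-1800
        # read bases: 0-99 exon1, 100-129 exon2, 130-229 exon3
        read = LongRead("r1", "A" * 230)
        # wrong long mapping: exon2's 30 bases forced into the intron right
        # after exon1, broken by two small deletions; exon3 correct
        long_rec = sam_factory("r1", "chr1", 1000, "110M2D10M1D10M567N100M",
                               read.sequence)
        # windows covering exon2 place it correctly (30M at 1400)
        win1 = sam_factory("r1|80", "chr1", 1080, "20M300N30M270N30M",
                           read.sequence[80:160])
        win2 = sam_factory("r1|100", "chr1", 1400, "30M270N50M",
                           read.sequence[100:180])
        aln = assemble_alignment(read, [long_rec], [win1, win2])
        keys = [j.key for j in aln.junctions]
        assert keys == [("chr1", 1100, 1400), ("chr1", 1430, 1700)]

    def test_fusion_read_two_segments(self, sam_factory):
        read = LongRead("r1", "A" * 200)
        primary = sam_factory("r1", "chr1", 1000, "100M100S", read.sequence)
        supp = sam_factory("r1", "chr2", 5000, "100S100M", read.sequence,
                           supplementary=True)
        aln = assemble_alignment(read, [primary, supp])
        assert len(aln.segments) == 2
        assert {s.chrom for s in aln.segments} == {"chr1", "chr2"}


class TestBedIO:
    def test_round_trip(self, tmp_path, world, sim):
        long_map = {}
        for r in sim.long_records:
            long_map.setdefault(r.query_name, []).append(r)
        alns = [assemble_alignment(read, long_map[read.read_id])
                for read in sim.reads[:10]]
        path = tmp_path / "a.bed"
        write_bed12(alns, path)
        reloaded = {a.read_id: a for a in read_bed12(path)}
        for aln in alns:
            assert [s.exons for s in reloaded[aln.read_id].segments] == \
                [[tuple(e) for e in s.exons] for s in aln.segments]

    def test_junction_file_line_count(self, tmp_path, world, sim):
        """One line per (read, junction): shared junctions repeat per read."""
        long_map = {}
        for r in sim.long_records:
            long_map.setdefault(r.query_name, []).append(r)
        alns = [assemble_alignment(read, long_map[read.read_id])
                for read in sim.reads[:20]]
        path = tmp_path / "j.txt"
        n = write_junction_file(alns, path)
        assert n == sum(len(a.junctions) for a in alns)
        assert len(path.read_text().splitlines()) == n
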