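import numpy as np
import pytest

from tagkit.hybrid_align import Segment, SplicedAlignment
from tagkit.refio import GenomeRef, Junction
from tagkit.simulate import corrupt_junctions, simulate_reads, truth_alignment
from tagkit.splice_cnn import SpliceNet, encode_window
from tagkit.splice_correct import (SpliceWindow, adjust_junction, build_training_set,
                                   correct_alignment, site_window, train_model,
                                   wobble_candidates)


class TestEncodeWindow:
    def test_base_vectors(self):
        m = encode_window("ACGTN" + "A" * 16)
        assert m.shape == (21, 4)
        assert m[0].tolist() == [1, 0, 0, 0]
        assert m[1].tolist() == [0, 1, 0, 0]
        assert m[2].tolist() == [0, 0, 1, 0]
        assert m[3].tolist() == [0, 0, 0, 1]
        assert m[4].tolist() == [0, 0, 0, 0]  # N -> zero vector

    def test_all_n_zero_matrix(self):
        assert not encode_window("N" * 21).any()

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            encode_window("A" * 20)
        with pytest.raises(ValueError):
            encode_window("X" + "A" * 20)


class TestSiteWindow:
    def test_plus_donor_content(self):
        # exon 0-30, intron starts at 30 with GT
        g = GenomeRef({"chr1": "A" * 30 + "GT" + "C" * 30 + "AG" + "T" * 30})
        j = Junction("chr1", 30, 64, "+")
        w = site_window(g, j, "donor", 10)
        assert w.label == 10
        assert w.seq[:10] == "A" * 10 and w.seq[10:12] == "GT"

    def test_plus_acceptor_content(self):
        g = GenomeRef({"chr1": "A" * 30 + "GT" + "C" * 30 + "AG" + "T" * 30})
        w = site_window(g, Junction("chr1", 30, 64, "+"), "acceptor", 10)
        assert w.label == 11
        assert w.seq[9:11] == "AG" and w.seq[11:] == "T" * 10

    def test_minus_strand_transcription_oriented(self):
        # reverse-complement world: forward CT...AC is GT-AG on minus
        g = GenomeRef({"chr1": "T" * 30 + "CT" + "G" * 30 + "AC" + "A" * 30})
        w = site_window(g, Junction("chr1", 30, 64, "-"), "donor", 10)
        assert w.seq[:10] == "T" * 10 and w.seq[10:12] == "GT"

    def test_edge_padding(self):
        g = GenomeRef({"chr1": "GT" + "C" * 30 + "AG" + "A" * 5})
        w = site_window(g, Junction("chr1", 0, 34, "+"), "donor", 10)
        assert w.seq[:10] == "N" * 10  # off-chromosome bases padded


class TestTrainingSet:
    def test_split_and_structure(self, world):
        train, val = build_training_set(world.db, world.genome, seed=3,
                                        samples_per_site=2)
        n = len(train) + len(val)
        assert len(val) == int(round(0.1 * n))
        for w in train[:50]:
            assert len(w.seq) == 21
            assert 1 <= w.n_exonic <= 10
            assert w.label == (w.n_exonic if w.side == "donor" else 21 - w.n_exonic)

    def test_donor_window_boundary(self, world):
        """An N=10 donor window has 10 exonic bases then the intron (GT...)."""
        junctions = {j.key: j for iso in world.db.isoforms.values()
                     for j in iso.junctions}
        j = junctions[min(junctions)]
        w = site_window(world.genome, j, "donor", 10)
        assert w.seq[10:12] == "GT"

    def test_seeded_determinism(self, world):
        a = build_training_set(world.db, world.genome, seed=5)
        b = build_training_set(world.db, world.genome, seed=5)
        assert [w.seq for w in a[0]] == [w.seq for w in b[0]]
        assert [w.label for w in a[1]] == [w.label for w in b[1]]

    def test_no_junctions_errors(self, toy_genome):
        from tagkit.refio import Isoform, IsoformDB
        db = IsoformDB([Isoform("t", "g", "chr1", "+", ((0, 500),))])
        with pytest.raises(ValueError):
            build_training_set(db, toy_genome)


@pytest.fixture(scope="module")
def tiny_model(world):
    train, _ = build_training_set(world.db, world.genome, seed=3,
                                  samples_per_site=1)
    return train, train_model(train[:200], epochs=3, channels=8, seed=3)


class TestModel:

    def test_output_distribution(self, tiny_model):
        train, model = tiny_model
        probs = model.predict_proba(train[:10])
        assert probs.shape == (10, 21)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_training_determinism(self, tiny_model):
        train, model = tiny_model
        again = train_model(train[:200], epochs=3, channels=8, seed=3)
        for a, b in zip(model.nets[0].params(), again.nets[0].params()):
            assert np.array_equal(a[1], b[1])

    def test_save_load_round_trip(self, tiny_model, tmp_path):
        train, model = tiny_model
        path = tmp_path / "model.npz"
        model.save(path)
        from tagkit.splice_correct import SpliceModel
        loaded = SpliceModel.load(path)
        assert np.allclose(loaded.predict_proba(train[:5]),
                           model.predict_proba(train[:5]))

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            train_model([])


class TestWobbleCandidates:
    def test_repeat_creates_candidates(self):
        # exon | GTA...AG | GTA exon: first 3 exon bases repeat the intron head,
        # so the junction can wobble 3 bases to the right
        g = GenomeRef({"chr1": "C" * 20 + "GTA" + "T" * 20 + "AG" + "GTA" + "C" * 20})
        cands = wobble_candidates(g, Junction("chr1", 20, 45, "+"), radius=15)
        starts = sorted(c.start for c in cands)
        assert starts == [20, 21, 22, 23]

    def test_no_repeat_single_candidate(self):
        g = GenomeRef({"chr1": "C" * 20 + "GT" + "T" * 20 + "AG" + "A" * 20})
        cands = wobble_candidates(g, Junction("chr1", 20, 44, "+"), radius=15)
        assert len(cands) == 1

    def test_negative_radius_errors(self):
        g = GenomeRef({"chr1": "A" * 50})
        with pytest.raises(ValueError):
            wobble_candidates(g, Junction("chr1", 10, 30), radius=-1)


class TestAdjustJunction:
    @pytest.fixture()
    def wobble_world(self):
        """Genome where the annotated junction has two rightward wobble
        placements; only the annotated one is canonical."""
        from tagkit.refio import Isoform, IsoformDB
        seq = "C" * 50 + "GTA" + "T" * 30 + "CAG" + "GTA" + "C" * 50
        g = GenomeRef({"chr1": seq})
        j_start, j_end = 50, 86
        db = IsoformDB([Isoform("t1", "g1", "chr1", "+", ((0, j_start), (j_end, 130)))])
        return g, db, Junction("chr1", j_start, j_end, "+")

    def test_annotated_junction_unchanged(self, wobble_world):
        g, db, j = wobble_world
        assert adjust_junction(None, g, db, j).key == j.key

    def test_shifted_junction_restored_without_model(self, wobble_world):
        g, db, j = wobble_world
        shifted = Junction(j.chrom, j.start + 2, j.end + 2, "+")
        assert adjust_junction(None, g, db, shifted).key == j.key

    def test_canonical_preferred_without_annotation(self, wobble_world):
        g, _, j = wobble_world
        shifted = Junction(j.chrom, j.start + 2, j.end + 2, "+")
        # no database: the canonical-motif rule alone restores the junction
        assert adjust_junction(None, g, None, shifted).key == j.key


class TestCorrectAlignment:
    def test_annotated_alignment_unchanged(self, world, sim):
        read_id = next(r for r in sim.truths if sim.truths[r].junction_keys)
        aln = truth_alignment(sim.truths[read_id])
        out = correct_alignment(None, world.genome, world.db, aln)
        assert [s.exons for s in out.segments] == [s.exons for s in aln.segments]

    def test_monoexonic_unchanged(self, world):
        aln = SplicedAlignment("r", [Segment("chr1", "+", [(300, 600)], 0, 300)], 300, 300)
        out = correct_alignment(None, world.genome, world.db, aln)
        assert out.segments[0].exons == [(300, 600)]

    def test_corruption_restored_and_counts_preserved(self, world, sim):
        """Wobble-shifted junctions (<=5 bp) are restored by the deterministic
        fallback; junction count and segments never change."""
        rng = np.random.default_rng(17)
        restored = total_shifted = 0
        for truth in sim.truths.values():
            if not truth.junction_keys:
                continue
            aln = truth_alignment(truth)
            corrupted, shifted = corrupt_junctions(world.genome, aln, rng, max_shift=5)
            out = correct_alignment(None, world.genome, world.db, corrupted, radius=5)
            assert len(out.junctions) == len(aln.junctions)
            assert len(out.segments) == len(aln.segments)
            total_shifted += shifted
            if shifted and {j.key for j in out.junctions} == truth.junction_keys:
                restored += 1
        assert total_shifted > 0
        assert restored > 0


def test_fallback_is_deterministic(world, sim):
    read_id = next(r for r in sim.truths if sim.truths[r].junction_keys)
    aln = truth_alignment(sim.truths[read_id])
    rng = np.random.default_rng(5)
    corrupted, _ = corrupt_junctions(world.genome, aln, rng)
    a = correct_alignment(None, world.genome, world.db, corrupted)
    b = correct_alignment(None, world.genome, world.db, corrupted)
    assert [s.exons for s in a.segments] == [s.exons for s in b.segments]
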