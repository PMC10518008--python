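import numpy as np
import pysam
import pytest

from tagkit.refio import GenomeRef, Isoform, IsoformDB
from tagkit.simulate import WorldConfig, make_world, simulate_reads


@pytest.fixture(scope="session")
def world():
    """Small deterministic synthetic world shared across tests."""
    return make_world(WorldConfig(n_genes=20), seed=11)


@pytest.fixture(scope="session")
def sim(world):
    return simulate_reads(world, n_reads=60, seed=12, truncate_frac=0.25)


@pytest.fixture(scope="session")
def toy_db():
    """Hand-built two-gene annotation on one chromosome (coordinates chosen
    so every interval is easy to reason about in tests)."""
    isoforms = [
        # geneA: 3 exons, one skip variant
        Isoform("A.t1", "geneA", "chr1", "+", ((100, 400), (500, 700), (800, 1100))),
        Isoform("A.t2", "geneA", "chr1", "+", ((100, 400), (800, 1100))),
        # geneB: 2 exons, minus strand
        Isoform("B.t1", "geneB", "chr1", "-", ((2000, 2300), (2500, 2800))),
        # geneC: monoexonic
        Isoform("C.t1", "geneC", "chr1", "+", ((4000, 4600),)),
    ]
    return IsoformDB(isoforms)


@pytest.fixture(scope="session")
def toy_genome(toy_db):
    rng = np.random.default_rng(99)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=6000)))
    # canonical motifs for the annotated junctions
    for iso in toy_db.isoforms.values():
        for j in iso.junctions:
            if j.strand == "+":
                seq[j.start:j.start + 2] = "GT"
                seq[j.end - 2:j.end] = "AG"
            else:
                seq[j.start:j.start + 2] = "CT"
                seq[j.end - 2:j.end] = "AC"
    return GenomeRef({"chr1": "".join(seq)})


@pytest.fixture()
def sam_factory():
    """Build in-memory SAM records against a simple two-chromosome header."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 100000}, {"SN": "chr2", "LN": 100000}],
    })

    def make(name, chrom, start, cigar, seq, reverse=False, supplementary=False,
             secondary=False):
        rec = pysam.AlignedSegment(header=header)
        rec.query_name = name
        rec.query_sequence = seq
        rec.reference_id = header.get_tid(chrom)
        rec.reference_start = start
        rec.cigarstring = cigar
        rec.mapping_quality = 60
        rec.flag = ((16 if reverse else 0) | (2048 if supplementary else 0)
                    | (256 if secondary else 0))
        return rec

    make.header = header
    return make
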