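"""Local splice-site adjustment.

Spliced aligners often place a junction a few bases off when the sequence
flanking the intron repeats across the boundary ("junction wobble"): several
placements explain the read equally well at the base level.  This module
enumerates the wobble-equivalent placements within a small radius and ranks
them, either with a boundary-offset CNN trained on annotated splice sites or
with a deterministic fallback (annotated junction first, then canonical motif,
then the original placement).  The fallback is the pipeline's "no-CNN" mode.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .refio import CANONICAL_MOTIFS, GenomeRef, IsoformDB, Junction, junction_motif, revcomp
from .hybrid_align import SplicedAlignment
from . import splice_cnn
from .splice_cnn import SpliceNet, encode_window

DEFAULT_RADIUS = 15
DONOR_SCORE_N = 10  # exonic bases in the scoring window; boundary offset 10
ACCEPTOR_SCORE_LABEL = 21 - DONOR_SCORE_N  # boundary offset 11


@dataclass
class SpliceWindow:
    """A 21-base training window: ``n_exonic`` transcript bases followed by
    intron (donor side) or intron followed by exon (acceptor side); the label
    is the boundary offset within the window."""

    seq: str
    label: int
    side: str  # "donor" | "acceptor"
    n_exonic: int

    def __post_init__(self):
        if not 1 <= self.label <= 20:
            raise ValueError("boundary offset must lie inside the window")

    @property
    def onehot(self) -> np.ndarray:
        return encode_window(self.seq)


def site_window(
    genome: GenomeRef, junction: Junction, side: str, n_exonic: int
) -> SpliceWindow:
    """Extract the transcription-oriented 21-bp window around one splice site.

    Donor windows contain the last ``n_exonic`` bases of the upstream exon then
    the intron start; acceptor windows the intron end then the first
    ``n_exonic`` bases of the downstream exon.  Out-of-chromosome overhangs are
    N-padded."""
    if not 1 <= n_exonic <= 20:
        raise ValueError("n_exonic out of range")
    chrom, start, end, strand = junction.chrom, junction.start, junction.end, junction.strand
    if side == "donor":
        label = n_exonic
        if strand == "+":
            seq = genome.fetch(chrom, start - n_exonic, start - n_exonic + 21, pad=True)
        else:
            seq = revcomp(genome.fetch(chrom, end - (21 - n_exonic), end + n_exonic, pad=True))
    elif side == "acceptor":
        label = 21 - n_exonic
        if strand == "+":
            seq = genome.fetch(chrom, end - (21 - n_exonic), end + n_exonic, pad=True)
        else:
            seq = revcomp(genome.fetch(chrom, start - n_exonic, start - n_exonic + 21, pad=True))
    else:
        raise ValueError(f"unknown side {side!r}")
    return SpliceWindow(seq, label, side, n_exonic)


def build_training_set(
    db: IsoformDB,
    genome: GenomeRef,
    seed: int = 0,
    samples_per_site: int = 3,
    validation_fraction: float = 0.1,
) -> tuple[list[SpliceWindow], list[SpliceWindow]]:
    """Labelled windows around every annotated splice site, 90/10 split.

    For each junction, donor and acceptor windows are drawn with the number of
    exonic bases N uniform on 1..10, so the boundary lands at offsets 1..10
    (donor) and 11..20 (acceptor)."""
    junctions: dict[tuple[str, int, int], Junction] = {}
    for iso in db.isoforms.values():
        for j in iso.junctions:
            junctions.setdefault(j.key, j)
    if not junctions:
        raise ValueError("annotation has no junctions to train on")
    rng = np.random.default_rng(seed)
    windows: list[SpliceWindow] = []
    for key in sorted(junctions):
        j = junctions[key]
        for side in ("donor", "acceptor"):
            for n in rng.integers(1, 11, size=samples_per_site):
                windows.append(site_window(genome, j, side, int(n)))
    order = rng.permutation(len(windows))
    n_val = max(1, int(round(validation_fraction * len(windows))))
    val = [windows[i] for i in order[:n_val]]
    train = [windows[i] for i in order[n_val:]]
    return train, val


class SpliceModel:
    """Ensemble of trained nets; predictions average the member softmaxes."""

    def __init__(self, nets: Sequence[SpliceNet]):
        if not nets:
            raise ValueError("model needs at least one trained net")
        self.nets = list(nets)

    def predict_proba(self, windows: Sequence[SpliceWindow]) -> np.ndarray:
        x = np.stack([w.onehot for w in windows])
        probs = np.zeros((len(windows), splice_cnn.N_CLASSES))
        for net in self.nets:
            probs += net.forward(x, train=False)
        return probs / len(self.nets)

    def accuracy(self, windows: Sequence[SpliceWindow]) -> float:
        probs = self.predict_proba(windows)
        labels = np.array([w.label for w in windows])
        return float((probs.argmax(axis=1) == labels).mean())

    def save(self, path: str) -> None:
        arrays = {"n_nets": np.array(len(self.nets)), "version": np.array(1)}
        for i, net in enumerate(self.nets):
            for k, v in net.state().items():
                arrays[f"net{i}_{k}"] = v
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "SpliceModel":
        d = np.load(path)
        nets = []
        for i in range(int(d["n_nets"])):
            prefix = f"net{i}_"
            state = {k[len(prefix):]: d[k] for k in d.files if k.startswith(prefix)}
            nets.append(SpliceNet.from_state(state))
        return cls(nets)


def train_model(
    train: Sequence[SpliceWindow],
    epochs: int = 50,
    lr: float = 0.01,
    batch_size: int = 64,
    repeats: int = 1,
    channels: int = 50,
    seed: int = 0,
) -> SpliceModel:
    """Train the boundary-offset classifier (``repeats`` independently seeded
    nets, averaged at prediction time)."""
    if not train:
        raise ValueError("empty training set")
    x = np.stack([w.onehot for w in train])
    y = np.array([w.label for w in train])
    nets = []
    for r in range(repeats):
        net = SpliceNet(channels=channels, seed=seed + 1000 * r)
        splice_cnn.train_net(net, x, y, epochs=epochs, lr=lr, batch_size=batch_size,
                             seed=seed + 1000 * r + 1)
        nets.append(net)
    return SpliceModel(nets)


def wobble_candidates(
    genome: GenomeRef, junction: Junction, radius: int,
    left_bound: Optional[int] = None, right_bound: Optional[int] = None,
) -> list[Junction]:
    """All junction placements within ±radius whose shift preserves the exact
    read-to-genome base correspondence (the moved bases repeat across the
    intron).  ``left_bound``/``right_bound`` clamp shifts so flanking exons
    keep at least one base."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    chrom, d, a = junction.chrom, junction.start, junction.end
    clen = genome.lengths[chrom]
    out = [junction]
    for delta in range(1, radius + 1):  # shift right: exon tail grows
        if a + delta > clen or (right_bound is not None and a + delta >= right_bound):
            break
        if genome.fetch(chrom, d, d + delta) != genome.fetch(chrom, a, a + delta):
            break
        out.append(Junction(chrom, d + delta, a + delta, junction.strand))
    for delta in range(1, radius + 1):  # shift left
        if d - delta < 0 or (left_bound is not None and d - delta <= left_bound):
            break
        if genome.fetch(chrom, d - delta, d) != genome.fetch(chrom, a - delta, a):
            break
        out.append(Junction(chrom, d - delta, a - delta, junction.strand))
    return sorted(out, key=lambda j: j.start)


def _model_score(model: SpliceModel, genome: GenomeRef, junction: Junction) -> float:
    dwin = site_window(genome, junction, "donor", DONOR_SCORE_N)
    awin = site_window(genome, junction, "acceptor", DONOR_SCORE_N)
    probs = model.predict_proba([dwin, awin])
    return float(probs[0, DONOR_SCORE_N] * probs[1, ACCEPTOR_SCORE_LABEL])


def adjust_junction(
    model: Optional[SpliceModel],
    genome: GenomeRef,
    db: Optional[IsoformDB],
    junction: Junction,
    radius: int = DEFAULT_RADIUS,
    left_bound: Optional[int] = None,
    right_bound: Optional[int] = None,
    canonical: Sequence[str] = CANONICAL_MOTIFS,
) -> Junction:
    """Pick the best wobble-equivalent placement of one junction.

    With a model: argmax of donor-window x acceptor-window probability, ties
    broken by annotated-junction match, canonical motif, leftmost.  Without a
    model (deterministic fallback): annotated match, then canonical motif,
    then the original placement."""
    cands = wobble_candidates(genome, junction, radius, left_bound, right_bound)
    if len(cands) == 1:
        return cands[0]

    def annotated(j: Junction) -> bool:
        return db is not None and j.key in db.junction_set

    def is_canonical(j: Junction) -> bool:
        try:
            return junction_motif(genome, j, canonical)[1]
        except ValueError:
            return False

    if model is not None:
        scored = [
            (-_model_score(model, genome, j), not annotated(j), not is_canonical(j), j.start, j)
            for j in cands
        ]
    else:
        scored = [
            (0.0, not annotated(j), not is_canonical(j), j.start != junction.start, j.start, j)
            for j in cands
        ]
    scored.sort(key=lambda t: t[:-1])
    return scored[0][-1]


def correct_alignment(
    model: Optional[SpliceModel],
    genome: GenomeRef,
    db: Optional[IsoformDB],
    aln: SplicedAlignment,
    radius: int = DEFAULT_RADIUS,
    canonical: Sequence[str] = CANONICAL_MOTIFS,
) -> SplicedAlignment:
    """Adjust every junction of an alignment; exon boundaries follow, junction
    count and chromosome segments are preserved."""
    out = copy.deepcopy(aln)
    for seg in out.segments:
        for i in range(len(seg.exons) - 1):
            old = Junction(seg.chrom, seg.exons[i][1], seg.exons[i + 1][0], seg.strand)
            new = adjust_junction(
                model, genome, db, old, radius,
                left_bound=seg.exons[i][0], right_bound=seg.exons[i + 1][1],
                canonical=canonical,
            )
            seg.exons[i] = (seg.exons[i][0], new.start)
            seg.exons[i + 1] = (new.end, seg.exons[i + 1][1])
    return out
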