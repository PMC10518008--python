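"""Gene-fusion calling from annotated reads and somatic filtering.

Fusion-class reads are grouped by ordered gene pair and by breakpoint
proximity (default ±10 bp per side).  A call is somatic when it has at least
one supporting transcript backed by >= 2 CCS reads and the matched normal
sample contributes no read supporting the same fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotate import AnnotationRecord

DEFAULT_BP_TOL = 10
DEFAULT_MIN_CCS_CLUSTER = 2


@dataclass
class FusionCall:
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    strand5: str
    chrom3: str
    pos3: int
    strand3: str
    supporters: list[tuple[str, int]] = field(default_factory=list)  # (read_id, ccs)
    somatic: Optional[bool] = None

    @property
    def n_supporting(self) -> int:
        return len(self.supporters)

    @property
    def max_ccs(self) -> int:
        return max((c for _, c in self.supporters), default=0)

    def matches(self, gene5: str, gene3: str, pos5: int, pos3: int, tol: int) -> bool:
        return (
            self.gene5 == gene5
            and self.gene3 == gene3
            and abs(self.pos5 - pos5) <= tol
            and abs(self.pos3 - pos3) <= tol
        )


def _fusion_key(rec: AnnotationRecord) -> Optional[tuple]:
    if rec.tclass != "Fusion" or len(rec.fusion_sides) < 2:
        return None
    a, b = rec.fusion_sides[0], rec.fusion_sides[-1]
    return (a.gene_id, b.gene_id, a.chrom, a.breakpoint, a.strand,
            b.chrom, b.breakpoint, b.strand)


def call_fusions(
    records: Sequence[AnnotationRecord],
    bp_tol: int = DEFAULT_BP_TOL,
) -> list[FusionCall]:
    """Group fusion reads into calls by gene pair and breakpoint proximity.

    Reads are processed in read-id order; a read joins the first existing call
    whose breakpoints lie within the tolerance, otherwise it seeds a new call
    (so one gene pair can yield several calls, one per distinct breakpoint
    pair, reflecting fusion isoform diversity)."""
    calls: list[FusionCall] = []
    for rec in sorted(records, key=lambda r: r.read_id):
        key = _fusion_key(rec)
        if key is None:
            continue
        g5, g3, c5, p5, s5, c3, p3, s3 = key
        target = None
        for call in calls:
            if call.chrom5 == c5 and call.chrom3 == c3 and call.matches(g5, g3, p5, p3, bp_tol):
                target = call
                break
        if target is None:
            target = FusionCall(g5, g3, c5, p5, s5, c3, p3, s3)
            calls.append(target)
        target.supporters.append((rec.read_id, rec.ccs_count))
    return calls


def somatic_filter(
    tumor_calls: Sequence[FusionCall],
    normal_records: Optional[Sequence[AnnotationRecord]],
    bp_tol: int = DEFAULT_BP_TOL,
    min_ccs_cluster: int = DEFAULT_MIN_CCS_CLUSTER,
) -> list[FusionCall]:
    """Somatic fusions: tumor calls with a supporting transcript of CCS count
    >= ``min_ccs_cluster`` and no supporting read in the matched normal.

    With no normal sample available, candidates passing the CCS rule are
    returned flagged unfiltered (``somatic is None``)."""
    candidates = [c for c in tumor_calls if c.max_ccs >= min_ccs_cluster]
    if normal_records is None:
        for c in candidates:
            c.somatic = None
        return candidates
    normal_keys = []
    for rec in normal_records:
        key = _fusion_key(rec)
        if key is not None:
            normal_keys.append(key)
    out = []
    for call in candidates:
        germline = any(
            call.chrom5 == c5 and call.chrom3 == c3
            and call.matches(g5, g3, p5, p3, bp_tol)
            for (g5, g3, c5, p5, _, c3, p3, _) in normal_keys
        )
        call.somatic = not germline
        if not germline:
            out.append(call)
    return out


def write_fusion_tsv(calls: Iterable[FusionCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene5\tgene3\tbreakpoint5\tbreakpoint3\tstrand5\tstrand3\t"
                 "n_supporting_transcripts\tmax_ccs\tsomatic\n")
        for c in calls:
            som = "." if c.somatic is None else str(c.somatic).lower()
            fh.write(
                f"{c.gene5}\t{c.gene3}\t{c.chrom5}:{c.pos5}\t{c.chrom3}:{c.pos3}\t"
                f"{c.strand5}\t{c.strand3}\t{c.n_supporting}\t{c.max_ccs}\t{som}\n"
            )
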