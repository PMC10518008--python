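"""Reference genome and transcript-annotation models.

Coordinates are 0-based half-open everywhere inside the package; GTF I/O
converts from/to the 1-based closed convention of that format.  A junction is
the intron interval ``[start, end)`` between two exons; junction identity is
exact coordinate identity (chromosome, start, end) so that matching against a
reference junction set is unambiguous after splice-site correction.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

VALID_BASES = set("ACGTN")

#: Canonical intron boundary dinucleotide pairs, transcription-oriented.
CANONICAL_MOTIFS = ("GT-AG", "GC-AG", "AT-AC")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeRef:
    """In-memory reference genome: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in {name!r}")
            self.sequences[name] = seq
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, pad: bool = False) -> str:
        """Sequence of ``[start, end)``; with ``pad`` out-of-range bases become N."""
        seq = self.sequences[chrom]
        if pad:
            left = "N" * max(0, -start)
            right = "N" * max(0, end - len(seq))
            return left + seq[max(0, start):max(0, min(end, len(seq)))] + right
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(f"{chrom}:{start}-{end} out of bounds (len {len(seq)})")
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def load_genome(fasta_path: str | os.PathLike) -> GenomeRef:
    """Parse a (possibly multi-record) FASTA into a :class:`GenomeRef`."""
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(fasta_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if name in sequences:
                        raise ValueError(f"duplicate chromosome {name!r}")
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                if not name:
                    raise ValueError(f"empty record name at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"sequence before header at line {lineno}")
                chunks.append(line)
    if name is None:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if name in sequences:
        raise ValueError(f"duplicate chromosome {name!r}")
    sequences[name] = "".join(chunks)
    return GenomeRef(sequences)


def write_genome(genome: GenomeRef, fasta_path: str | os.PathLike, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class Junction:
    """An intron ``[start, end)``; equality/hash ignore the strand so junction
    matching is pure coordinate matching."""

    chrom: str
    start: int
    end: int
    strand: str = field(default="+", compare=False)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"junction start must precede end: {self}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def donor(self) -> int:
        """Genomic coordinate of the first intronic base on the donor side
        (transcription-oriented: the intron start for +, intron end - 1 for -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def acceptor(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def junction_motif(
    genome: GenomeRef,
    junction: Junction,
    canonical: Sequence[str] = CANONICAL_MOTIFS,
) -> tuple[str, bool]:
    """Transcription-oriented boundary dinucleotides, e.g. ``"GT-AG"``.

    The two first and two last intronic bases are read from the forward strand
    and reverse-complemented for minus-strand junctions, so a spliceosomal
    intron always reports GT-AG regardless of the gene's orientation.
    """
    if junction.end - junction.start < 4:
        raise ValueError("intron too short for motif extraction")
    left = genome.fetch(junction.chrom, junction.start, junction.start + 2)
    right = genome.fetch(junction.chrom, junction.end - 2, junction.end)
    if junction.strand == "+":
        motif = f"{left}-{right}"
    else:
        motif = f"{revcomp(right)}-{revcomp(left)}"
    return motif, motif in set(canonical)


@dataclass
class Isoform:
    """A reference transcript model: ordered exons on one chromosome/strand."""

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise ValueError(f"isoform {self.isoform_id} has no exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in {self.isoform_id}")
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty exon in {self.isoform_id}")
        self.exons = exons

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple(
            Junction(self.chrom, e1, s2, self.strand)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcript start (5' end) in genome coordinates."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def pas(self) -> int:
        """Transcript end (3' end) in genome coordinates."""
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


class IsoformDB:
    """Annotation database with interval indexes for overlap queries."""

    def __init__(self, isoforms: Iterable[Isoform]):
        self.isoforms: dict[str, Isoform] = {}
        self.genes: dict[str, list[str]] = {}
        for iso in isoforms:
            if iso.isoform_id in self.isoforms:
                raise ValueError(f"duplicate isoform id {iso.isoform_id}")
            self.isoforms[iso.isoform_id] = iso
            self.genes.setdefault(iso.gene_id, []).append(iso.isoform_id)
        self.junction_set: set[tuple[str, int, int]] = set()
        self.donor_sites: set[tuple[str, int]] = set()
        self.acceptor_sites: set[tuple[str, int]] = set()
        self._iso_tree: dict[str, IntervalTree] = {}
        self._gene_tree: dict[str, IntervalTree] = {}
        gene_spans: dict[str, tuple[str, int, int]] = {}
        for iso in self.isoforms.values():
            s, e = iso.span
            self._iso_tree.setdefault(iso.chrom, IntervalTree()).addi(s, e, iso.isoform_id)
            if iso.gene_id in gene_spans:
                c, gs, ge = gene_spans[iso.gene_id]
                gene_spans[iso.gene_id] = (c, min(gs, s), max(ge, e))
            else:
                gene_spans[iso.gene_id] = (iso.chrom, s, e)
            for j in iso.junctions:
                self.junction_set.add(j.key)
                self.donor_sites.add((j.chrom, j.donor))
                self.acceptor_sites.add((j.chrom, j.acceptor))
        self.gene_spans = gene_spans
        for gid, (c, s, e) in gene_spans.items():
            self._gene_tree.setdefault(c, IntervalTree()).addi(s, e, gid)

    def __len__(self) -> int:
        return len(self.isoforms)

    def overlapping_isoforms(self, chrom: str, start: int, end: int) -> list[Isoform]:
        tree = self._iso_tree.get(chrom)
        if tree is None:
            return []
        ids = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.isoforms[i] for i in ids]

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def is_known_junction(self, junction: Junction) -> bool:
        return junction.key in self.junction_set

    def subset(self, gene_ids: Iterable[str]) -> "IsoformDB":
        keep = set(gene_ids)
        return IsoformDB(
            iso for iso in self.isoforms.values() if iso.gene_id in keep
        )


def load_annotation(gtf_path: str | os.PathLike, genome: GenomeRef | None = None) -> IsoformDB:
    """Load an Ensembl-dialect GTF (gene_id/transcript_id attributes required)."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        rec = exons.setdefault(
            tid, {"gene": gid, "chrom": ex.seqid, "strand": ex.strand, "exons": []}
        )
        rec["exons"].append((ex.start - 1, ex.end))  # GTF 1-based closed -> half-open
    if not exons:
        raise ValueError(f"no exon features found in {gtf_path}")
    isoforms = []
    for tid, rec in exons.items():
        if genome is not None:
            if rec["chrom"] not in genome:
                raise ValueError(f"unknown chromosome {rec['chrom']} for {tid}")
            clen = genome.lengths[rec["chrom"]]
            for s, e in rec["exons"]:
                if s < 0 or e > clen:
                    raise ValueError(f"exon {s}-{e} of {tid} outside {rec['chrom']}")
        isoforms.append(
            Isoform(tid, rec["gene"], rec["chrom"], rec["strand"], tuple(rec["exons"]))
        )
    return IsoformDB(isoforms)


def write_annotation(db: IsoformDB, gtf_path: str | os.PathLike, source: str = "tagkit") -> None:
    """Write gene/transcript/exon GTF records (1-based closed coordinates)."""
    with open(gtf_path, "w") as fh:
        for gid in sorted(db.genes):
            chrom, gs, ge = db.gene_spans[gid]
            strand = db.isoforms[db.genes[gid][0]].strand
            attrs = f'gene_id "{gid}";'
            fh.write(f"{chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n")
            for tid in sorted(db.genes[gid]):
                iso = db.isoforms[tid]
                s, e = iso.span
                tattrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(
                    f"{iso.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{iso.strand}\t.\t{tattrs}\n"
                )
                for es, ee in iso.exons:
                    fh.write(
                        f"{iso.chrom}\t{source}\texon\t{es + 1}\t{ee}\t.\t{iso.strand}\t.\t{tattrs}\n"
                    )
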