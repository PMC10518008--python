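# tagkit

Analysis toolkit for full-length transcript sequencing (PacBio Iso-seq / ONT
cDNA).  Long reads capture whole transcripts but their spliced alignments
misplace exons and splice sites often enough to corrupt isoform-level
conclusions.  `tagkit` is aimed at transcriptomics researchers who need, from
polished full-length transcripts: accurate spliced alignments, transcript
classification against a reference annotation, isoform-level expression and
differential isoform usage, and somatic gene-fusion calls.

## What it does

**Hybrid alignment assembly.** Each polished read `S = s₁…s_L` is scanned with
sliding windows of length `h = 250` at step `t = 100`; the window slices are
re-aligned as spliced short reads, giving every base of `S` up to `n + 1`
candidate genome positions with weight `ω = 1/nᵢ`.  Runs of uniquely mapped
bases are accepted directly; multiply-mapped blocks longer than 10 bp are
resolved by enumerating maximal colinear runs `A_τ` (quality `Q_τ = Σω`) and
choosing the combination maximising

```
Σ Q − μ₁·O − μ₂·k − μ₃·D₁ − μ₄·D₂        (μ = 2, 2, 1, 1)
```

where `O` is pairwise read overlap, `k` the number of runs chosen, and
`D₁`, `D₂` distances to the uniquely mapped anchors (set to 1000 across
chromosomes).  Gaps ≥ 20 bp between exon blocks become splice junctions.

**Splice-site correction.** Where flanking sequence repeats across an intron
boundary, several junction placements explain the read equally well ("wobble").
Candidates within ±15 bp are ranked either by a small CNN — three blocks of
3×3-kernel, 50-channel convolution with ReLU and batch normalisation over
one-hot 21-bp windows, trained with Adam (lr 0.01) on windows around annotated
splice sites (N exonic bases, N uniform on 1..10; 90/10 train/validation
split) — or by a deterministic fallback (annotated junction, then canonical
GT-AG/GC-AG/AT-AC motif, then original placement).

**Annotation.** The best-matching reference isoform maximises
`L_TI − θ₁·L_I − θ₂·L_T` (θ = 0.5, 0.5, exonic-base overlap), and each read
gets one of seven classes: FSM, ISM, NIC, NNC, Genic, Intergenic, Fusion
(junction spanning two genes, ≥ 20 bp mapped to each).

**Quantification.** Reads uniquely annotated to a known isoform are counted;
novel reads cluster by junction-chain containment.  Expression is TPT
(count × 100 000 / total transcripts).  Differential isoform usage filters
low-expressed genes (`Q = 4`, `P = 5 %`) and applies an exact test to each
gene's isoform-by-condition table with Benjamini–Hochberg FDR.  Transcripts
need ≥ 2 supporting CCS reads to enter the analysis.

**Fusions.** Fusion-class reads group by gene pair and breakpoint (±10 bp);
somatic calls need one supporter with ≥ 2 CCS reads and no support in the
matched normal.

**Simulation.** `tagkit.simulate` generates genomes with realistic splice-site
signal, reads with known truth (alignments, classes, junctions), reduced
annotations for the deletion protocol, and fusion datasets — so the whole
pipeline is testable without external aligners or downloads.

## Worked example

```bash
tagkit simulate reads --genes 20 --n-reads 60 --seed 5 --out-dir demo
tagkit align --fasta demo/reads.fa --long-sam demo/long.sam \
             --short-sam demo/short.sam --out-bed demo/aln.bed
tagkit correct --bed demo/aln.bed --genome demo/genome.fa \
               --gtf demo/annotation.gtf --no-cnn --out-bed demo/corrected.bed
tagkit annotate --bed demo/corrected.bed --gtf demo/annotation.gtf \
                --genome demo/genome.fa --out demo/annotation.tsv
```

which prints

```
60 reads -> demo
aligned 60/60 reads -> demo/aln.bed
corrected 60 alignments -> demo/corrected.bed
annotated 60 reads -> demo/annotation.tsv
```

`demo/annotation.tsv` then holds one row per read, e.g.

```
read_id     class  best_match   genes    n_junctions  n_novel_junctions  ccs_count
read00000   FSM    gene013.t2   gene013  2            0                  1
```

meaning read00000's junction chain matches all junctions of isoform
`gene013.t2` with both ends within 100 bp — a full splice match with no novel
junctions.  The same stages are available as a single `tagkit run --config
cfg.yaml`, which also writes gene/transcript TPT tables, the per-read junction
file and the fusion table.

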