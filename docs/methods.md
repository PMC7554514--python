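# Methods

This note records the models behind each `heatscreen` module, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would want
written down.

## Two-library exact test (`tag_dge`)

Model: per-gene tag counts are Poisson; conditional on a gene's combined
count, the count in library 2 follows a negative-binomial mass with
success probability `N₂/(N₁+N₂)`, giving

    p(y|x) = (N₂/N₁)^y · (x+y)!/(x!·y!) · (1+N₂/N₁)^−(x+y+1).

The two-sided p-value doubles the lower cumulative sum (or its
complement when it exceeds ½) and is clipped at 1. We evaluate the
cumulative sum with vectorized log-gamma terms and `logsumexp` rather
than the naive term recurrence: the two are algebraically identical, but
the log-space sum remains accurate when the first term underflows
(e.g. x in the thousands). The test suite checks agreement with an
exact rational-arithmetic evaluation to 1e−10 relative error over all
x, y ≤ 50 at library ratios ½, 1 and 2.

Decisions:

* **FDR procedure.** Benjamini–Hochberg step-up (the standard choice
  for DGE screens), via `statsmodels`; Benjamini–Yekutieli available
  through `method="fdr_by"`.
* **Fold change** is computed on library-size-normalized counts —
  `((y+c)/N₂)/((x+c)/N₁)` — since the totals are integral to the test.
  Default pseudocount c = 0: a zero count in library 1 gives an infinite
  fold that passes the fold filter; both counts zero gives an undefined
  (NaN) fold and the gene never qualifies.
* **Direction** is library 2 over library 1 (treated over control), so
  "up" means higher in the treated library.
* The discrete test is conservative: under a null simulation the
  fraction of p ≤ α stays at or below α (asserted at α = 0.05, 0.01 on
  10,000 genes).

## Count-matrix screen (`count_de`)

RPKM is `counts·10⁹/(length_bp·total)`; with totals equal to column
sums, `Σ_g RPKM·length(kb) = 10⁶` per sample (asserted at 1e−6 relative
tolerance). Scaling factors are median-of-ratios against the gene-wise
geometric-mean reference, excluding genes with any zero, renormalized
to geometric mean 1; when no gene is all-positive the code falls back to
library-size factors with a warning.

The DEG screen applies the exact two-library test to scaling-normalized
counts summed within each group and rounded to integers. This is a
deliberate, documented stand-in for a negative-binomial GLM with
dispersion shrinkage: it shares the screen's defining arithmetic
(normalization, log2 fold change, the `p_adj < 0.05` and `|log₂FC| > 1`
thresholds) but not the replicate-level dispersion modeling, so its
p-values are anti-conservative when biological replicates are
overdispersed. Pooling is adequate for the planted-effect recovery and
null-behavior properties the tests assert; for real replicate data a
dedicated NB GLM package is the right tool.

Report tables round log2 fold changes half-away-from-zero to two
decimals. Of the fifteen published readcount-pair examples this package
reproduces, ten match the printed two-decimal value exactly from the
plain ratio; the remaining five differ by ≤ 0.03, consistent with the
printed readcounts being rounded normalized means. The worked-example
tests pin the ten reproducible pairs.

## Enrichment (`enrichment`)

Upper-tail hypergeometric p per pathway with overlap > 0; q-values are
BH-adjusted p (the common operational definition of "Q-value" in
over-representation tools). The universe defaults to the union of the
gene sets and is configurable; query genes outside it are dropped and
reported. Top-k overlap uses a stable sort on (q, p, pathway_id) so ties
are deterministic.

## Sequence screens (`seq_screen`)

* Coordinates are 0-based half-open internally; file interfaces use
  1-based inclusive coordinates (stated in their docstrings).
* The DRE/CRT core is the IUPAC pattern `RCCGAC` = [A/G]CCGAC; the
  named 9-mers DRE1 `GACCGACGA`, DRE2 `AGCCGACAC`, DRE3 `CGCCGACTT`
  and the mutant control mDRE `TATTTTCAT` are scanned as literals.
  All (overlapping) matches on both strands are reported in
  forward-strand coordinates; deduplication is left to consumers.
* Promoters default to 2000 bp upstream of the gene start (a common
  regulatory-window convention; configurable), reverse-complemented for
  minus-strand genes so the output reads 5′→3′ toward the gene, and are
  truncated with a warning at contig edges.
* Domain search is iterated Smith–Waterman (Biopython's
  `PairwiseAligner`, BLOSUM62, gap open 11 / extend 1 — the classic
  protein-alignment defaults): report the best local hit, mask it,
  repeat while the score clears `min_score`. The default
  `min_score = 80` sits far above what random ~60-residue queries score
  against unrelated protein sequence (tests assert zero hits on
  domain-free simulated proteins) and far below an intact domain copy
  (~300 for the packaged consensus), so 0/1/2 planted copies are
  recovered exactly even at 10% point mutation.
* The packaged AP2 consensus (`data/ap2_consensus.synthetic.fa`) is a
  synthetic ~60-residue stand-in with AP2/ERF-like composition; tests
  use it for planting and recovery so no external profile database is
  required. For real screens, supply your own consensus FASTA.
* CDS translation requires a triplet length, warns on a non-ATG start,
  errors on internal stops (naming the codon), and drops a terminal
  stop, so a 579-nt CDS encodes 192 residues.

## Phylogeny (`phylo`)

p-distance is the default model (gap-containing columns excluded
pairwise); Poisson correction `−ln(1−p)` is available by flag. NJ is the
standard Saitou–Nei agglomeration; ties in the Q-minimization break on
the lowest (i, j) index pair, so output is platform-independent.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling edge. On additive matrices NJ recovers the
generating topology and exact leaf-to-leaf path lengths; the tests
assert this for 4–8 taxa against trees with known structure (a
construction oracle — enumerating all unrooted topologies would check
the same property at far greater cost) and cross-check the topology
against an independent NJ implementation (scikit-bio) when available.

Bootstrap resamples alignment columns with replacement, rebuilds the NJ
tree per replicate, and reports for each internal bipartition of the
full-data tree the percentage of replicates containing it. 1,000
replicates is the conventional default; tests use fewer for speed.

## Quantification and phenotyping (`quant`)

2^−ΔΔCt: replicate Ct values are averaged per (sample, gene) before
ΔCt (averaging first is the common lab convention; the alternative —
per-replicate RQ — changes only the error propagation, not the point
estimate). The calibrator's RQ is 1 by construction. Adding a constant
to one sample's target and reference Cts leaves its RQ unchanged
(asserted).

Heat injury index: plants are scored on ordinal levels 0..max_level
(default 3: none / partial curling / heavy curling / fully wilted) and

    HII(%) = Σ(count_level · level) · 100 / (max_level · total).

HII is bounded in [0, 100], is 0 (100) when all plants are at the
bottom (top) level, and moving any plant up a level never decreases it.

Replicate summaries use the equal-variance Student's t-test (Welch by
flag), sample SD (n−1), and star labels `**`/`*` at p < 0.01 / 0.05.
Two identical constant groups report p = 1.

## Synthetic data (`simulate`)

Generators emulate the *statistical structure* of the screen's inputs:

* **Tag libraries / count matrices** — log-normal expression profile
  (σ = 1.3, a typical bulk-transcriptome spread) scaled to the library
  size; DE genes (a Bernoulli fraction) have group-2 means multiplied by
  2^±effect. Counts are Poisson, or gamma-Poisson with
  `variance = μ + dispersion·μ²` (dispersion 0 recovers the Poisson
  tag-DGE model). Defaults: 10,000 genes, 10% DE, |log₂FC| = 2,
  10⁶ tags/library — the scale of a two-library DGE experiment.
* **Promoters** — i.i.d. uniform ACGT background (GC configurable) with
  elements planted at recorded positions/strands.
* **Proteins** — random 20-letter backgrounds with 0/1/2 consensus
  copies, each residue mutated independently at the given rate.
* **Ct tables** — target Ct shifted by −log₂(RQ) against the
  calibrator, constant reference gene, 3 replicate wells, Gaussian
  cycle noise.
* **Injury tallies** — multinomial over levels.
* **Alignments** — Jukes–Cantor evolution along a supplied tree
  (branch lengths in substitutions/site).

Each generator draws from a stream derived from the global seed plus a
fixed per-generator stream id, so adding a generator never perturbs the
others; identical seed and configuration give byte-identical output, and
every dataset ships a machine-readable truth table.

What the generators do **not** emulate: tag-to-gene mapping and
sequencing error (simulation starts at per-gene counts), GC or
mappability bias, correlated gene expression, amplification-efficiency
drift in qPCR, and indel/heterotachy processes in alignments. Passing
recovery tests on these data therefore validates the *inference
arithmetic*, not robustness to those real-data artifacts.

## Problem sizes in the test suite

The acceptance-level property tests run at desk scale on one CPU: a
10,000-gene null screen for type-I error, a 5,000-gene planted screen
for sensitivity, exhaustive hypergeometric enumeration to universe size
30, exact-test oracle comparison over all x, y ≤ 50 at three library
ratios, 1,000 random 200-nt sequences for the motif scanner, 4–8-taxon
additive matrices for NJ, and 40-replicate ΔΔCt recovery grids. The
entire suite completes in well under a minute.
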