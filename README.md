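# heatscreen

A toolkit for the computational side of a heat-stress gene-discovery
screen in plants: finding stress-responsive transcription factors (such
as DREB-family AP2/ERF proteins) from two-library tag-based digital gene
expression (DGE) profiles, characterizing them by count-matrix fold
changes and pathway enrichment, sequence-level screens for DRE/CRT
cis-elements and AP2 domains, neighbor-joining phylogeny, qPCR
quantification, and heat-injury phenotyping. Every pipeline stage has a
matching synthetic-data generator with known ground truth, so the whole
screen can be exercised and validated without any external dataset.

Intended users: plant molecular biologists and bioinformaticians running
or re-analyzing DGE/RNA-seq stress screens, and anyone who needs a small,
tested, scriptable implementation of these classic methods.

## The methods

**Two-library exact test** (`heatscreen.tag_dge`). A gene with *x* clean
tags out of *N₁* total in library 1 and *y* of *N₂* in library 2 is
tested for equal expression with the conditional Poisson model
(Audic–Claverie):

```
p(y|x) = (N₂/N₁)^y · (x+y)! / (x!·y!) · (1 + N₂/N₁)^−(x+y+1)
```

The two-sided p-value is `2·S` with `S = Σ_{i≤y} p(i|x)`, or `2·(1−S)`
when `S > ½`, clipped to [0, 1]. Candidate genes satisfy FDR ≤ 0.001
(Benjamini–Hochberg) and a normalized fold change > 2 in either
direction.

**Count-matrix analysis** (`heatscreen.count_de`). RPKM normalization
(`counts · 10⁹ / (length_bp · total)`), median-of-ratios scaling factors,
log2 fold changes between group means, and a DEG screen at
`p_adj < 0.05` and `|log₂FC| > 1` (exact test on scaling-normalized
pooled counts as a documented stand-in for a NB GLM).

**Enrichment** (`heatscreen.enrichment`). Upper-tail hypergeometric
over-representation `P(X ≥ k)` for a query of *n* genes against a
pathway of *K* genes in a universe of *N*, BH-adjusted q ≤ 0.05, plus
top-k pathway-overlap comparison between ranked lists. GMT in/out.

**Sequence screens** (`heatscreen.seq_screen`). CDS translation, IUPAC
motif scanning on both strands for the DRE/CRT core `[A/G]CCGAC` and the
named DRE1/DRE2/DRE3/mDRE 9-mers, strand-aware promoter extraction,
iterated Smith–Waterman (BLOSUM62) domain search with a
single-AP2-domain filter, and tandem-repeat bait construction for
yeast one-hybrid vectors.

**Phylogeny** (`heatscreen.phylo`). p-distance (or Poisson-corrected)
matrices, Saitou–Nei neighbor joining with deterministic tie-breaking,
column-bootstrap bipartition supports, newick output.

**Quantification & phenotyping** (`heatscreen.quant`). Relative
expression by 2^−ΔΔCt against a reference gene and calibrator sample;
the heat injury index

```
HII(%) = Σ(plants at level · level) · 100 / (max level · total plants)
```

over ordinal injury scores 0–3; replicate summaries with Student's
t-test star labels.

## Worked example

Simulate a two-library heat-stress DGE experiment with 10% of 2,000
genes truly differentially expressed at |log₂FC| = 2, then screen:

```bash
cat > sim.yaml <<EOF
n_genes: 2000
de_fraction: 0.1
effect_log2: 2.0
library_sizes: [1000000, 1000000]
EOF
heatscreen simulate tags --config sim.yaml --out demo --seed 42
heatscreen tagdge demo/tags.tsv --fdr 0.001 --fold 2 --out demo/dge.tsv
# candidates: 106 up, 94 down
```

The screen calls 200 candidate genes (106 up-, 94 down-regulated).
Scoring against the sidecar truth table `demo/tags.truth.tsv` (206 genes
were planted as DE) gives a sensitivity of 0.971 — the exact test plus
the FDR ≤ 0.001 / fold > 2 filter recovers almost all planted 4-fold
effects at this depth while calling essentially nothing under the null.

The same pattern works for the other stages, e.g.:

```bash
heatscreen scan-dre promoters.fa            # DRE element hits, both strands
heatscreen hii tally.tsv --max-level 3      # heat injury index in %
heatscreen phylo aln.fa --boot 1000 --seed 7
```

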