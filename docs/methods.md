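# Methods

## Expression model and transforms

All analyses operate on a genes × cells matrix of non-negative,
RPKM-scale expression values. Network correlations, eigengenes,
heterogeneity correlations and gene–area correlations are computed on
`log2(RPKM + 1)`; RPKM is heavy-tailed and the log stabilizes Pearson
correlation against a handful of highly expressed genes. Every entry
point that transforms accepts `log_transform=False` for callers who
have already transformed (or who want raw-scale correlations, whose
behaviour differs and is their responsibility).

Quality control mirrors common single-cell RNA-seq practice for
full-length protocols: a cell passes when *strictly more* than
`min_genes` (default 5,000) genes exceed RPKM 0.1 (strict `>` on both
counts), and a gene is analysed when expressed at RPKM ≥ 10
(*inclusive*) in at least `min_cells` cells (default 1) — a deliberate
asymmetry: the cell filter guards against failed libraries, the gene
filter only removes genes that never reach a quantifiable level.
Heterogeneity correlations use a stricter gene set (RPKM ≥ 10 in ≥ 20%
of cells, the ceiling of the fraction) so that cell–cell correlations
are not dominated by dropout zeros.

## Signed co-expression network

The adjacency is the standard signed soft-thresholding map

    a_ij = ((1 + r_ij) / 2)^β,

which sends r = 1 → 1, r = 0 → 2^−β and r = −1 → 0, preserving the
sign of co-regulation (anti-correlated genes are *not* connected). β is
chosen as the smallest integer in 1..20 whose scale-free topology fit
reaches 0.8; the fit statistic is the signed R² (−sign(slope)·R²) of
the regression of log10 p(k) on log10 k over ten equal-width bins of
the whole-network connectivity k_i = Σ_j a_ij. Degenerate inputs
(constant genes, all-equal correlations) make the fit undefined for
every power and raise rather than silently picking a β.

Topological overlap is used as the clustering similarity:

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

with ω_ii = 1 and dissimilarity 1 − ω. A flag (`use_tom=False`)
substitutes 1 − a.

### Tree cut

Genes are clustered by average linkage on the TOM dissimilarity. The
cut is a recursive fixed-height rule operating on each subtree:

1. Sever the subtree at `cut_height_fraction` (default 0.99) × its own
   maximum merge height — at minimum the top merge.
2. If the cut produces two or more branches of at least
   `min_module_size` genes (default 20), the split is real: recurse
   into each substantial branch; fragments below the floor become
   unassigned.
3. Otherwise the subtree is kept whole as one module.

The height reference is the subtree *maximum*, not a quantile of the
merge-height distribution: in expression data most merges belong to
unstructured background genes and pile up in a narrow band just below
the dendrogram top, so any distribution quantile lands inside that band
and returns a single giant cluster, whereas a fraction of the maximum
reliably severs the loose top-level merges. Because a fixed-height cut
can halve a legitimate module, halves are rejoined afterwards whenever
two modules' eigengenes correlate above `module_merge_corr` (default
0.9 — far above the correlation of distinct transcriptional programs,
far below that of two halves of one program, which share a latent
factor). Finally, membership is cleaned: genes whose kME (correlation
with their module's eigengene) falls below `min_kme` (default 0.3) are
unassigned, and modules dropping under the size floor dissolve. The
cleanup is what lets loose branches keep background genes during
cutting without contaminating the final modules, and what removes the
occasional spurious all-background "module" (a 20-gene noise cluster's
members correlate with their own first principal component at ~0.2).

Modules under `merge_min_genes` (default 30) genes are then merged into
the module of floor size or above whose eigengene correlates best with
theirs, smallest module first, ties by label; when no module reaches
the floor everything merges into the largest one with a warning.

### Eigengenes, kME, hubs

A module eigengene is the first right singular vector of the per-gene
z-scored module submatrix — a unit-norm profile over cells — oriented
so the mean correlation with member genes is positive; variance
explained is s₁²/Σs². Single-gene modules degenerate to the gene's own
z-scored profile and are flagged. Projection of new cells re-uses the
training per-gene means, standard deviations and gene weights
(score = zᵀu/s₁), so projecting the training cells reproduces the
training eigengenes exactly; absent genes are imputed at z = 0 with a
warning and a module with under half its genes present is flagged
unreliable. Node centrality is the sum of within-module adjacency
(unassigned genes score 0); hub genes are the top-ranked members.

## Cell classification

Cells are clustered on their module-eigengene profiles with complete
linkage on correlation distance (1 − r between feature vectors), cut
into k groups; clusters below ⌈0.05·n⌉ cells are dissolved into the
surviving cluster with the most correlated centroid (waived below 20
cells), and labels are renumbered by size.

**Module selection.** A Random Forest (1,000 trees) predicts the
cluster labels from the eigengene matrix augmented with a permuted
("shadow") copy of every module; a module scores a hit when its
impurity importance beats the *maximum* shadow importance. Eleven
seeded rounds are run with fresh shadow permutations, and a module is
selected when it dominates in ≥ 90% of rounds. The strict threshold
matters: a noise module that correlates with the labels by chance
trades places with the shadow maximum across rounds, while a genuinely
informative module never loses to a shadow; with a simple majority
rule, dataset-lucky noise modules slip through.

**Cluster number.** For each k in 4..10 a forest's out-of-bag (OOB)
error is measured against the k-cluster labels. Two details are
deliberate:

- The sweep clusters with the size floor *disabled*. With the floor
  active, the extra clusters produced past the true number are small,
  get dissolved, and the labels — hence the error — become identical
  for every k past the truth, erasing the very increase the sweep looks
  for. The floor applies to the final clustering at the chosen k.
- The chosen k is the edge of the low plateau: the largest k whose
  error is below `drastic_factor` (default 2) × the error floor while
  the next k's error is not, taking the first such edge. The floor is
  the minimum error over the range but never below 2/n (two cells), so
  a near-zero plateau does not turn one-cell jitter into a "drastic"
  increase. If the curve never leaves the plateau, the error carries no
  evidence for extra clusters and the smallest k within two cells of
  the minimum is returned.

**Allocation and composition.** New cells are assigned by a forest
trained on the reference cells' selected-module eigengenes, with vote
fractions reported. Composition differences between groups (e.g.,
genotypes) use the two-sided Fisher exact test on the group × cluster
table: full enumeration of all tables with the observed margins for
totals ≤ 60, otherwise seeded Monte-Carlo sampling (Patefield's
algorithm, 10⁵ tables) with the add-one correction. t-SNE embedding
(perplexity 10, seeded) is provided for reporting only.

## Stage-specific modules

The network is fitted twice with identical parameters: on all cells
and on all cells minus one stage. Each full-network module is matched
against every reduced-network module with a one-sided Fisher exact
test (hypergeometric upper tail) on the 2×2 membership table over the
shared gene universe; unassigned genes stay in the universe but belong
to no module. A module whose best match falls below
`threshold_neglogp` (default 10 on −log10 p; fully configurable and
reported in output) has no counterpart without that stage's cells and
is flagged stage-specific. Raw p-values are reported alongside
Bonferroni-adjusted ones over all pairs; flagging uses the raw
threshold. Cross-dataset comparison translates one dataset's labels
through a 1:1 ortholog map (non-bijective entries dropped and counted)
and runs the same overlap test.

## Morphology integration

PCA of cells uses per-gene z-scored log expression; the sign convention
fixes each component's largest-magnitude gene loading positive. PCs,
module eigengenes and single genes are ranked by Pearson correlation
with cell area; gene ranking requires detection (RPKM > 0.1) in at
least one cell, ties break lexicographically, zero-variance profiles
report NaN and sort last, and constant area raises.

## Synthetic data

The generator draws log2-scale expression
`x_gc = b_g + Σ_m L_gm f_mc + ε_gc`, with baselines b_g uniform on
(2, 6) (RPKM ~3–60), loadings L_gm ~ N(1.0, 0.3) inside contiguous
module blocks and 0 outside, factors f_mc ~ N(stage_activity[m,
stage(c)], 1), and noise ε ~ N(0, 1.0). The reported matrix is
`2^x − 1` clipped at 0 with 10% magnitude-independent dropout. Cell
area is `baseline + α·f·baseline/10 + N(0, σ_area)` (baseline 3,000
µm², σ 150 µm², α 0.8 for the coupled module). A stage-specific module
is *silent* (factor exactly 0) outside a Bernoulli-selected subset of
one stage's cells — the point of the construct is that its
co-expression signal exists only while those cells are in the dataset —
and its activation is strong (mean 5 on log2, ~30-fold), as for a
stress-response burst. Cluster ground truth is the set of distinct
factor-mean patterns realized per cell.

The default configuration mirrors the profiled cohort: 10,000 genes
and 396 cells over six stages (sham 64, day 3 58, week 1 82, week 2
61, week 4 73, week 8 58), eight modules of 30–150 genes. The test
and acceptance benchmarks are scaled-down named conditions, chosen once
as study conditions:

- `module_recovery_config` — 2,000 genes × 300 cells, five modules of
  50–150 genes, stage-patterned activity of amplitude 2.
- `stage_specific_config` — 800 genes × 240 cells, three global
  modules plus the 80-gene burst module active in 30% of week-2 cells.
- `seven_cluster_config` — 1,200 genes × 480 cells, seven cell states:
  six with strong marker modules (amplitude 6) and a larger, looser
  baseline state (120 cells, amplitude 3). The loose baseline is what
  the k = 8 cut carves, reproducing the drastic OOB error increase
  past the true cluster number; with seven equally tight states the
  8th cut strips only a few outlier cells and the error curve stays
  flat.
- `morphology_config` — 600 genes × 300 cells, α = 0.8 area coupling.

What the generator does *not* emulate: UMI counting noise,
magnitude-dependent dropout, batch effects, doublets, gene-length
effects, or continuous trajectories between states (factor means are
piecewise-constant per stage). Passing tests therefore demonstrate
that the pipeline recovers planted linear-factor structure at
realistic noise — not that real cardiomyocyte data meet those
assumptions.

## Numerical conventions

Determinism: identical seeds give bit-identical generator output; all
forest, Monte-Carlo and embedding seeds are explicit; pipeline stage
seeds derive from the top-level seed by CRC hashing of the stage name,
so partial reruns reproduce each stage independently. Ties break
lexicographically by gene/module id throughout (merge targets, hub
ranking, top-gene lists). Zero-variance genes are dropped with a
warning before network construction (the adjacency itself raises, so
the model surface cleans and the primitive stays strict). Exact Fisher
enumeration compares log-probabilities with a 1e-9 slack to keep
floating-point ties in the two-sided tail.

## Limitations

- The tree cut is a simplified dynamic cut; it does not implement the
  full dynamic-hybrid branch analysis, and very unequal module
  correlation structure (two programs correlating above ~0.6 at low β)
  can leave them merged.
- Module counts depend on the cut and merge thresholds; only planted
  recovery, not absolute module numbers, is validated.
- The stage-specific construct detects modules whose co-expression
  requires one stage's cells; it cannot distinguish "active only in
  stage X" from "variance concentrated in stage X" more finely.
- Forest out-of-bag error at small n (a few hundred cells) has
  multi-cell jitter; the chosen-k rule is robust to one-cell noise but
  the k decision near the plateau edge can move by one on unlucky
  draws.
- RPKM normalization is taken as given; no attempt is made to model
  library-size or length biases.
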