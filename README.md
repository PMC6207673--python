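# cardiomod

Co-expression module analysis of single-cardiomyocyte transcriptomes.

Pressure overload drives heart muscle cells from adaptive hypertrophy
into failure, and bulk RNA-seq averages away the cell-to-cell
heterogeneity that marks this transition. `cardiomod` re-implements, as
a tested and reusable Python pipeline, the module-level analysis of
single-cardiomyocyte RPKM expression matrices sampled along a
pressure-overload time course (sham, day 3, weeks 1–8):

- **Quality control** — cells kept when more than 5,000 genes are
  detected at RPKM > 0.1; genes kept at RPKM ≥ 10 in at least one cell;
  cell-to-cell transcriptional heterogeneity as within-stage pairwise
  Pearson correlations.
- **Signed weighted co-expression network** — adjacency
  `a_ij = ((1 + r_ij)/2)^β` on log2(RPKM+1) profiles with β chosen by
  scale-free topology fit, topological overlap (TOM) dissimilarity,
  average-linkage clustering with a recursive fixed-height tree cut,
  merging of modules under 30 genes, module eigengenes (first principal
  component of each module), kME module membership and hub genes by
  within-module connectivity.
- **Cell classification** — hierarchical clustering of cells on
  eigengene profiles (correlation distance, complete linkage, minimum
  cluster size 5% of cells), classification-significant modules by a
  shadow-feature Random-Forests criterion, the cluster number chosen
  from an out-of-bag error sweep over k = 4..10, allocation of new
  cells to predetermined clusters, and Fisher's exact test for group
  composition differences.
- **Stage-specific modules** — the network is built twice, with and
  without one stage's cells; full-network modules with no significant
  Fisher-overlap counterpart in the reduced network are flagged as
  requiring that stage. The same machinery compares module sets across
  datasets through an ortholog map.
- **Morphology integration** — PCA of cells and Pearson correlation of
  principal components, module eigengenes and single genes with
  measured cell area (µm²), including top-N area-correlated gene lists.
- **Synthetic data** — a latent-factor generator
  (`x_gc = b_g + Σ_m L_gm f_mc + ε_gc` on the log2 scale, reported as
  `2^x − 1` with dropout) that plants modules, stage-patterned factor
  activity, cell clusters, a burst-active stage-specific module and an
  area-coupled factor, with full ground truth, so every stage of the
  pipeline is testable without external data.

## Worked example

```python
from cardiomod import CoexpressionNetwork
from cardiomod.simulate import module_recovery_config, simulate_cells

matrix, meta, truth = simulate_cells(module_recovery_config(seed=1))
net = CoexpressionNetwork(matrix).fit()
print(net.summary())
```

```
        n_genes  variance_explained hub_gene
module
M1          134            0.413421   G00038
M2          116            0.480492   G00188
M3          100            0.550920   G00273
M4           59            0.385171   G00396
M5           50            0.540714   G00468
```

The benchmark dataset plants five modules of 150/120/100/70/50 genes in
a 2,000-gene × 300-cell matrix; the fit recovers them as M1–M5 (1,541
background genes stay unassigned), each eigengene explaining 39–55% of
its module's variance, with the soft power β = 9 selected
automatically. `net.module_correlation()` exposes the module-to-module
structure (e.g., M1 and M3 planted with opposing stage patterns
correlate at −0.54), and `net.labels`, `net.eigengenes`, `net.kme` and
`net.hub_genes()` carry the full assignment.

Clustering cells on eigengene profiles and sweeping the cluster number
(here on the seven-state benchmark):

```python
from cardiomod import ModuleClassifier
clf = ModuleClassifier(eigengenes, k_range=range(4, 11), seed=0).fit()
print(clf.summary())
```

```
    oob_error  chosen
4    0.010417   False
5    0.014583   False
6    0.014583   False
7    0.010417    True
8    0.029167   False
9    0.045833   False
10   0.052083   False
```

The out-of-bag error stays at ~1% for k = 4..7 and roughly triples at
k = 8, so k = 7 is chosen — the planted number of cell states. New
cells are then allocated with `clf.allocate(new_eigengenes)` and group
compositions compared with `clf.composition_test(group_labels)`.

A `cardiomod` command-line interface mirrors each stage (`simulate`,
`qc`, `network`, `classify`, `stage-specific`, `morphology`, `run`);
`cardiomod run --config cfg.yaml` executes the full pipeline and writes
a JSON manifest with checksums, parameters and per-stage summaries.

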