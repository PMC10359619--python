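# coexnet

Weighted gene co-expression network analysis (WGCNA) in Python: build a
weighted network from an expression matrix, find modules of co-expressed
genes or transcripts, summarize each module by its eigengene, relate
modules to sample traits, and compare module sets across networks or
against external gene lists.

It is aimed at transcriptomics analysts working with normalized bulk or
pseudo-bulk RNA-seq matrices (samples × genes) who want the classic
correlation-network module workflow as an importable, scriptable Python
library with a small CLI, plus a fully controlled synthetic-data
generator for validating every step.

## The method

Starting from a complete samples × genes matrix **X**:

1. **Correlation.** Pairwise gene correlation `r_ij` (Pearson, or
   biweight midcorrelation for outlier robustness).
2. **Soft thresholding.** Adjacency
   `a_ij = ((1 + r_ij)/2)^β` (signed; `|r|^β` unsigned,
   `r^β·1[r>0]` signed-hybrid). β is chosen as the smallest candidate
   for which the network's degree distribution is approximately
   scale-free: signed `R²` of the regression of log₁₀ frequency on
   log₁₀ connectivity `k_i = Σ_{j≠i} a_ij` exceeds a cutoff
   (default 0.9).
3. **Topological overlap.** With `L_ij = Σ_{u≠i,j} a_iu a_uj`,

   `TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   blending direct adjacency with shared-neighbour structure;
   `1 − TOM` is the clustering dissimilarity.
4. **Modules.** Average-linkage hierarchical clustering of `1 − TOM`,
   cut adaptively (branch size, core scatter, and gap criteria
   controlled by `deep_split`, with an optional PAM-like reassignment
   stage). Genes in no module get the conventional grey/0 label.
5. **Eigengenes.** Each module is summarized by the first principal
   component of its standardized submatrix (zero-mean, unit-variance
   per sample, sign-oriented along mean expression); close modules
   (eigengene correlation > 0.75 by default) are merged iteratively.
6. **Downstream.** Module–trait correlation with t-test p-values and
   Benjamini–Hochberg adjustment, eigengene summaries per metadata
   category, module membership `kME_ij = cor(x_i, E_j)`, hub genes, and
   cross-network module overlap (Jaccard index, shared-gene fractions,
   one-sided Fisher exact test against a gene universe).

## Worked example

`examples/01_simulate_and_detect.py` simulates 50 samples × 350 genes —
three planted 100-gene modules (within-module correlation 0.7, one
latent factor per module) plus 50 pure-noise genes — and runs the whole
pipeline:

```
simulated 50 samples x 350 genes (3 planted modules + 50 background)
detected modules and sizes: {0: 50, 1: 100, 2: 100, 3: 100}
adjusted Rand index vs planted truth: 1.000
per-module best-match Jaccard: {1: 1.0, 2: 1.0, 3: 1.0}
```

All three modules are recovered exactly, and all 50 background genes
are left unassigned (label 0): the detected partition is identical to
the planted one (ARI 1.0). The other example scripts demonstrate soft
threshold selection (`02`), module–trait statistics and hub genes
(`03`), and cross-network module comparison with the Jaccard > 0.05
filter (`04`).

The same pipeline runs from the shell:

```bash
coexnet simulate --seed 0 --out sim/
coexnet run --expr sim/expression.csv --out run/
coexnet compare --a runA/module_assignment.tsv --b runB/module_assignment.tsv \
    --universe union --out cmp/
```

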