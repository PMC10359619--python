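# Methods

## Scope and data model

coexnet operates on a complete (no missing values) samples × features
matrix of normalized expression. Normalization, batch correction, and
any log transform are the caller's responsibility: every downstream
step is correlation-based and therefore scale-sensitive, and the
package deliberately performs no transformation beyond per-feature
standardization inside the eigengene computation. Missing values are
tolerated at ingestion (recorded as NaN, never as zero) but must be
removed by QC filtering before network construction; network operations
reject incomplete matrices outright rather than silently falling back
to pairwise deletion, so every correlation is computed on the same
sample set.

## QC filtering

Two independent feature rules: total expression across samples below
`min_total_expression` (default 1, appropriate for non-negative
abundance data), and fraction of entries that are missing or ≤ 0 above
`max_missing_fraction` (default 0.5). Both rules are evaluated against
the input dataset, which makes filtering idempotent. Outlier samples
are detected by average-linkage hierarchical clustering of samples
under Euclidean distance; the tree is cut at a user-chosen height and
only the largest cluster is retained. A tie for the largest cluster is
an error by design — silently discarding an arbitrary half of a cohort
is not acceptable QC — and sample removal is disabled unless a cut
height is given. Note that the abundance-oriented defaults are wrong
for data that is already centered (e.g. the simulator's output, which
is zero-mean by construction); such data should be run with the
thresholds disabled.

## Network construction

Correlation is Pearson by default; biweight midcorrelation (Tukey
biweight weights around the median, 9×MAD scaling, with a mean/SD
fallback for zero-MAD features) is available for outlier robustness.
Adjacency types follow the standard conventions: unsigned `|r|^β`,
signed `((1+r)/2)^β` (the default, because it keeps strongly
anti-correlated genes out of the same module), signed-hybrid
`r^β·1[r>0]`.

The soft power β is selected by the scale-free topology criterion.
Connectivities are binned into 10 equal-width bins; empty bins are
dropped and log₁₀ frequency is regressed on log₁₀ mean connectivity
per bin. Equal-width binning is required for this fit to be defined at
all: equal-occupancy bins have constant frequency by construction and
degenerate the regression. The fit statistic is R² signed by the
slope, so only decreasing degree distributions count as scale-free.
`pick_soft_threshold` chooses the smallest candidate power (defaults:
1–10, 12, 14, 16, 18, 20) whose signed R² reaches `fit_cutoff`
(default 0.9), and otherwise reports the best-fitting power with a
warning. The pipeline layer treats that fallback differently: small or
strongly modular datasets often carry no scale-free signal, making the
max-R² power an unstable, near-arbitrary pick (it can land at β = 1
and blur module boundaries), so `build_network` substitutes the
sample-size-based default power used throughout the field — unsigned
9/8/7/6 for < 20 / < 30 / < 40 / ≥ 40 samples, doubled for signed
networks — whenever the cutoff is not reached.

TOM uses the standard formula
`TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with the diagonal
fixed at 1, computed as one matrix product on the zero-diagonal
adjacency; an optional `block_size` evaluates the product in row
blocks to bound peak memory on large matrices with bit-identical
results. The result is symmetrized by averaging with its transpose to
cancel float round-off in the matmul. For non-negative adjacencies the
signed and unsigned TOM variants coincide, since the signed variant
only takes absolute values. The correctness of the vectorized form is
checked against a literal triple-loop evaluation in the test suite and
the acceptance script.

## Module detection

Features are clustered by average linkage on `1 − TOM` (scipy's
implementation; merge heights are non-decreasing, which the replay
below relies on). Modules are read off the dendrogram by the package's
adaptive branch cut:

1. Merges are replayed bottom-up; merges above `cut_height`
   (default 0.99 × top merge height) are never applied. Heights are
   normalized to [0, 1] between the 5th percentile of merge heights
   and `cut_height`.
2. Each growing branch records every member's joining height. When two
   branches meet at height h, each is asked whether it is a bona fide
   cluster: at least `min_module_size` members (default 30), core
   scatter (mean normalized joining height of its lowest-joining
   `min_module_size` members) at most `max_core_scatter`, and gap
   `h_norm − top internal height` at least `min_gap`. If both qualify,
   both are committed as modules; otherwise they coalesce. A branch
   that meets an already-committed composite without qualifying
   dissolves into unassigned features.
3. `deep_split` ∈ 0..4 interpolates `max_core_scatter` over
   (0.64, 0.73, 0.82, 0.91, 0.95) with
   `min_gap = (1 − max_core_scatter)·3/4`; higher values split more
   aggressively. Default 2.
4. Branches still separate at `cut_height` are evaluated on size and
   core scatter only: the static cut itself already separates them, and
   requiring an additional gap there double-counts the evidence (it
   also makes module calls hostage to a single late-joining straggler).
5. Each module is trimmed: members whose joining height exceeds
   median + 3·1.4826·MAD of the module's joining heights revert to
   unassigned.
6. With `pam_stage` on (default), an unassigned feature joins the
   module with the smallest average dissimilarity only if that average
   (a) strictly beats the feature's average dissimilarity to all other
   features and (b) does not exceed the module's radius (the largest
   member-to-co-members average dissimilarity). Condition (b) exists
   because condition (a) alone absorbs pure-noise features: among
   several modules, one is always nearest by chance.

Modules are labelled 1..M by decreasing size (0 = unassigned, rendered
"grey"; other labels map to the conventional module color sequence).
`min_module_size` larger than the feature count yields an all-
unassigned labelling with a warning, not an error.

## Eigengenes and merging

A module's eigengene is the first left singular vector of its
standardized (per-feature z-score, ddof = 1) samples × features
submatrix, scaled to zero mean and unit sample variance, with
`variance_explained = s₁²/Σs²`. The sign is oriented so the eigengene
correlates non-negatively with the module's mean standardized
expression; with a fixed linear-algebra backend the computation is
bit-for-bit reproducible. Modules whose eigengenes are closer than
`merge_cut_height` (default 0.25 in 1 − correlation units, i.e.
correlation > 0.75) are merged greedily: each round merges the single
closest pair and recomputes all eigengenes, repeating until no pair is
close enough. Recomputing every round keeps the result independent of
merge order; `merge_cut_height = 0` never merges (the comparison is
strict).

## Module statistics

Categorical traits are one-hot encoded — one 0/1 indicator per level —
because correlating against arbitrary integer codes is meaningless;
the encoding map is returned with the results. For each (module,
trait) cell, r is the Pearson correlation of eigengene and trait,
p is two-sided from `t = r·√((n−2)/(1−r²))` on n−2 df, and adjustment
is Benjamini–Hochberg across the entire module × trait grid (the
screening use-case; per-trait adjustment can be done on the returned
raw p-values). Constant traits produce NaN cells with a warning.
`kME` is the correlation of each feature with each module eigengene;
intramodular connectivity sums adjacency within the feature's own
module. Hub genes are ranked by kME to their own module, then
intramodular connectivity, then feature id (a deterministic total
order).

## Module comparison

Every (module A, module B) pair gets the shared count, Jaccard index,
shared fraction of each set, and a Fisher exact test against a gene
universe. The test is one-sided enrichment — the hypergeometric upper
tail P(X ≥ n_shared) — because the use-case is finding conserved
modules; a two-sided option exists. The universe is an explicit,
mandatory parameter (union of both collections by default,
intersection or an explicit list otherwise) since it materially changes
p-values; genes outside it are dropped with a warning and a set left
empty by that is an error. BH adjustment spans all pairs of one run.
The comparison filter keeps pairs with Jaccard strictly greater than
the threshold (default 0.05) and adjusted p at most alpha, yielding the
edge list of a module-conservation graph weighted by Jaccard. The
unassigned/grey gene sets are included as comparable sets by
`ModuleAssignment.as_sets()` by default and can be excluded.

## Synthetic data

The generator plants one latent factor per module: factor values are
standard normal per sample, and a member feature is
`x = λ f + noise_sd · ε` with `λ = noise_sd · √(ρ/(1−ρ))`, so the
expected within-module correlation is exactly ρ. Background features
are pure noise. Traits are linear responses `e·f + √(1−e²)·ε` (so e is
the factor–trait correlation), optionally dichotomized at the median
into case/control. Options: a shared component across factors
(`factor_correlation`) to create mergeable module pairs, and a loading
boost for each module's first feature to plant a known hub. All draws
derive from one master seed through `numpy.random.SeedSequence`
spawning, so factor, noise, and trait streams are independently
reproducible and same-seed runs are bit-identical.

Defaults — 50 samples, three modules of 100 features, 50 background
features, ρ = 0.7, unit noise — are the conditions used by the test
bench and the acceptance script (2–5 modules, 10 seeds each, for
recovery). What this generator does *not* emulate: count noise
(negative binomial), library-size and batch effects, correlated
background structure, heavy-tailed expression, or overlapping module
membership. Perfect recovery on this model therefore demonstrates the
pipeline's correctness, not its performance on real tissue data, where
module boundaries are far fuzzier.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and adjacency/TOM to [0, 1]
  after computation to absorb float round-off; symmetry of computed
  matrices is enforced within 1e−10 on input validation.
- Zero-variance features are a named error in correlation (and should
  be removed by QC); a degenerate all-equal connectivity vector is a
  named error in the scale-free fit.
- Ties in hub ranking break lexicographically by feature id; ties for
  the largest sample cluster in outlier removal are an error.
- Eigengene sign ties (exactly zero correlation with the mean profile)
  default to +1.
- p-values of perfectly correlated pairs are reported as exactly 0
  (the t statistic diverges).

## Known limitations

- Whole-matrix computation: correlation, adjacency, and TOM are dense
  n × n arrays; ~20k features ≈ 3.2 GB per matrix in float64. The
  blockwise TOM product bounds the intermediate, not the outputs.
- The adaptive tree cut is this package's normative algorithm — it
  follows the branch-qualification ideas of the dynamic tree cut
  family (size, core scatter, gap, PAM stage) but is not a line-for-line
  reimplementation, so module boundaries can differ from other
  implementations on the same data.
- One-factor module simulation gives analytic control but produces
  cleaner structure than real data; see the synthetic-data section.
- No consensus modules across networks, no blockwise pre-clustering
  for >memory datasets, no GO/pathway enrichment or PPI retrieval —
  per-module gene lists are exported in a form external enrichment
  tools consume.
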