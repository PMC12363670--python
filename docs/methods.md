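# Methods

This note documents the model, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Problem setting

Given a labeled reference atlas (cells × genes raw counts, one categorical
state label per cell) the package learns a discriminative map from expression
profile to cell state and applies it to unlabeled query datasets. States are
finer than cell types (e.g. two limbal-stem-cell states rather than one stem
compartment), class frequencies are strongly imbalanced (rare states can be
< 0.5% of cells), and query datasets may contain populations absent from the
reference. The design goals are: calibrated confidence rather than hard
labels, explainable per-state gene rankings, and bitwise reproducibility
given a seed.

## Preprocessing

* **Normalization.** Each cell is scaled to 10⁴ total counts and transformed
  `ln(1 + x)`. The target sum and transform are the field-standard choice and
  configurable (`normalize.target_sum`); all-zero cells are left at zero with
  a warning rather than dropped, so cell order is never silently changed.
* **Standardization.** Per-gene z-scores use the **reference** mean and
  population standard deviation of the normalized layer, for queries too.
  Re-estimating scale per query would leak query batch structure into the
  decision function; fixing reference statistics keeps the feature space
  constant across datasets. Z-scores are clipped at ±10 to bound the
  influence of outlier cells; zero-variance genes are set to 0 (they carry no
  information for a linear model).
* **Gene harmonization.** Queries are reindexed to the model's gene panel by
  exact symbol match (no alias mapping): missing genes are zero-filled,
  extras dropped. Annotation is refused when more than 50% of panel genes are
  missing (`harmonize.max_missing`) — beyond that the zero-filled features
  dominate and certainty scores lose meaning.
* **HVG annotation.** The top-2,000 genes by dispersion (variance/mean of the
  normalized layer, ties broken lexicographically) are flagged. The flag is
  reporting metadata only — feature selection starts from *all* genes, and
  the final panel's HVG / non-HVG composition is reported, since informative
  low-variance genes do survive selection.

## Classifier

One-vs-rest linear SVMs (hinge loss, L2 penalty) with defaults C = 0.01,
balanced class weights `N/(K·n_c)`, and a 1,000-iteration cap. Balanced
weights are essential for rare states; the iteration cap is part of the
model definition, and non-convergence within it is recorded in the training
report as a warning, never silenced. The binary special case is expanded into
two symmetric per-class discriminants so every class owns a decision score
for its calibrator. Hyperparameter tuning is an exhaustive grid scored by
stratified K-fold cross-validated weighted F1; ties break toward smaller C
(stronger regularization is the safer choice on sparse data), then balanced
weights, then fewer iterations.

Evaluation uses stratified shuffled K-fold (K = 5) with an explicit seed.
The headline metric is weighted F1, `Σ_c (n_c/N)·F1_c`; per-class
precision/recall/F1 are computed from pooled out-of-fold predictions.

## Shapley attributions and recursive feature elimination

For a linear decision function the Shapley value relative to a background
expectation `mu` is exact: `phi[x,g,k] = w[k,g]·(x[g] − mu[g])` with base
value `b[k] + w[k]·mu`. The efficiency identity
`base + Σ_g phi = decision score` is enforced by construction and verified to
1e-8 in tests. Gene importance aggregates as
`Σ_k mean_cells |phi[·,g,k]|`; because `|phi|` factorizes for linear models,
the implementation uses `Σ_k |w[k,g]| · mean_cells |x[·,g] − mu[g]|` and never
materializes the cells × genes × classes tensor (the two paths are
cross-checked in tests).

Elimination runs R = 4 rounds. Each round refits an interim SVM with the
final hyperparameters (no nested tuning — tuning once is the described
protocol, and nested tuning would add quadratic cost without a stated
benefit), computes importances over a seeded background subsample of up to
1,000 reference cells (the subsample mean is the background; a full-data
background adds cost but no information for a linear model), and retains the
top `ceil(f·m)` genes with f = 0.5, ties broken lexicographically by gene ID
so results are platform-independent. The default schedule takes a ~20k-gene
transcriptome to ~1.25k genes — a panel size at which marker sets for a few
dozen states fit comfortably while most of the transcriptome's noise genes
are gone; f is configurable for atlases that need a different endpoint.
Elimination stops early with a warning if the retained count would fall below
the number of classes.

## Calibration and certainty

Per class, a Platt sigmoid `P(y=c|s) = sigmoid(−(A·s + B))` is fitted by
L-BFGS-B on Platt-smoothed targets, with the constraint A ≤ 0 so every
calibrator is monotone non-decreasing in the decision score. Scores come from
an internal stratified K-fold split seeded independently of the evaluation
folds, so no calibrator is fitted on scores produced by a model that saw the
same cells. Sigmoid calibration was chosen over isotonic regression because
rare states provide too few positive points for a stable step function; the
choice matters exactly for the rare-state use case. A class whose out-of-fold
scores are all identical (e.g. a degenerate constant feature space) gets an
identity-like fallback sigmoid on the raw score plus a warning.

Per-cell class probabilities are the calibrated sigmoids renormalized to sum
to 1. The **certainty score** is the maximum renormalized probability —
consistent with a single confidence on a 0–1 scale — and is binned
low = [0, 0.3), medium = [0.3, 0.7), high = [0.7, 1]. The 0.3/0.7 edges are
the conventional reading thresholds for this kind of confidence score; the
half-open boundary assignment is this package's choice, fixed so that
binning of the exact boundary values is deterministic and documented.
Reliability curves (10 equal-width bins, per class) are stored in the
training report; expected calibration error is support-weighted
`Σ_b (n_b/N)·|acc_b − conf_b|` on the certainty score.

Argmax ties break toward the lexicographically smallest state name (the
vocabulary is sorted, and the first maximum wins).

## Explanations

Per predicted state *c*, attributions of class *c* are computed over the
query cells predicted as *c*, with the reference mean as background — which
is the origin of the standardized space, so `phi = w_c · x_std`. Genes are
ranked by mean attribution; only strictly positive values are kept and the
list is truncated to `n_top` (default 10). Explanations are computed on the
query, not the reference, so the table reflects what drove *these*
predictions. States with no predicted cells are omitted with a warning.

## Synthetic data generator

Counts are negative binomial with mean
`baseline[g] · F^{1[g marker of state]} · depth[cell]` and inverse-dispersion
θ = 2 (variance `mu + mu²/θ`): baselines log-normal(0, 1), per-cell depth
log-normal(0, 0.3), marker fold change F = 8 on disjoint per-state marker
sets. Queries reuse the atlas generative model and can add a per-gene
multiplicative log-normal batch shift and novel states with fresh marker
sets. The default preset has 15 states with one rare state at ~0.5% frequency
to exercise balanced class weights. Zero inflation is deliberately omitted:
at these means the NB alone reproduces scRNA-seq sparsity, and extra
parameters would not change what the tests can establish.

What the generator does **not** emulate: ambient RNA, doublets, batch effects
with gene–gene correlation structure, transcriptional continua between
states, or realistic gene–gene covariance. Passing the synthetic benchmarks
therefore demonstrates correctness of the pipeline's mechanics (selection
keeps discriminative genes, calibration tracks accuracy, novelty depresses
certainty) — not performance on real tissue, which depends on atlas quality
and cross-dataset effects the simulator idealizes away.

## Benchmark scales and test design

The test suite and `scripts/acceptance.py` use problem sizes chosen as the
smallest scales at which each property is statistically resolvable:

* end-to-end pipeline: 15 states × 200 cells × 2,000 genes (4 elimination
  rounds to a 125-gene panel, 5-fold CV);
* marker recovery: 40 planted markers among 2,000 genes, two rounds at
  f = 0.25 (125-gene panel), 5 seeds;
* calibration: 3,000 held-out cells, 10-bin ECE;
* permutation null: 15 balanced states × 60 cells, 10 label permutations;
* batch-shift property: a moderately separated atlas (8 markers/state,
  F = 6, 1,000 genes) — with near-saturated certainties the σ = 0.5 shift
  effect is smaller than query sampling noise, so the property is tested in
  the regime where it is identifiable;
* over-dispersion check: variance ≥ mean is asserted for genes with empirical
  mean ≥ 0.5 at 2,000 cells — below that floor the NB excess `mu²/θ` is
  smaller than the sampling noise of the variance estimator, so the
  inequality, while true in expectation, is not testable per gene.

## Reproducibility

Every stochastic step (simulation, fold shuffling, background subsampling,
solver initialization) takes an explicit seed; two runs with the same data,
config and seed produce byte-identical panels, model bundles and prediction
tables. Model bundles are single zip archives (JSON manifest + npz arrays)
with a format-version string; loading a bundle of a different version fails
loudly. Each CLI output directory contains one `manifest.json` with the tool
version, config snapshot, input hashes, seed and captured warnings.

## Known limitations

* No rejection option: novel populations are only signaled by low certainty,
  never labeled "unknown".
* Linear decision functions only; no kernel or deep models, hence the exact
  attribution story.
* Gene matching is exact string equality — cross-species or alias-divergent
  references must be harmonized upstream.
* The calibration quality reported on synthetic data is an upper bound: real
  query datasets with batch structure will generally be less well calibrated,
  which is precisely why certainty bins rather than raw probabilities are the
  recommended reading.
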