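# cellstate

Reference-based cell-state annotation for single-cell RNA-seq.

`cellstate` trains a calibrated multiclass linear classifier on a labeled
reference atlas (cells × genes counts plus one state label per cell) and uses
it to annotate query datasets with:

* a **predicted cell state** per cell,
* a **calibrated certainty score** in [0, 1], binned *low* (< 0.3),
  *medium* (0.3–0.7) or *high* (≥ 0.7),
* per-state tables of the **explainable genes** that drove the predictions.

It is aimed at labs that maintain a curated tissue atlas — including fine-grained
states and rare populations — and want to project new scRNA-seq datasets onto it
reproducibly from the command line or from Python. Populations absent from the
reference (for example immature states in organoid data) are not force-labeled;
they surface as depressed certainty scores.

## Method

The classifier is a one-vs-rest linear support-vector machine with hinge loss
and L2 regularization (defaults: C = 0.01, balanced class weights
`N/(K·n_c)`, 1,000 max iterations), trained on library-size-normalized
(`ln(1 + x)` at 10⁴ counts/cell), reference-standardized expression.

**Feature selection** is recursive elimination driven by Shapley attributions.
For a linear decision function the Shapley value of gene *g* for cell *x* and
class *k* is exact and closed-form:

```
phi[x, g, k] = w[k, g] · (x[g] − mu[g]),      base[k] = b[k] + w[k]·mu
```

so that `base + Σ_g phi` reproduces the decision score (efficiency). Each of
*R* rounds (default 4) fits an interim model, scores genes by
`Σ_k mean_cells |phi|` over a seeded background subsample, and retains the top
`ceil(f·m)` genes (default f = 0.5); from a ~20k-gene transcriptome four rounds
yield a panel near 1.2k genes. All genes enter round 1, so informative
non-highly-variable genes can survive into the final panel.

**Calibration** fits one Platt sigmoid per class on out-of-fold decision scores
from an internal stratified split; per-cell probabilities are renormalized to
sum to 1, and the certainty score is the maximum renormalized probability.
Model quality is reported as stratified 5-fold cross-validated weighted F1
with per-class precision/recall/F1 and per-class reliability curves.

A negative-binomial simulator (`cellstate.simulate`) generates labeled
atlases and queries with planted state-specific marker genes, library-size
variation, optional per-gene batch shift and novel states, so the whole
pipeline is testable without downloading any dataset.

## Worked example

```python
from cellstate import (CellStateModel, EliminationConfig, ModelConfig,
                       SimulationConfig, simulate_atlas, simulate_query)

cfg = SimulationConfig(n_states=5, cells_per_state=80, n_genes=400,
                       markers_per_state=8, seed=7)
atlas, markers = simulate_atlas(cfg)

model = CellStateModel(atlas, ModelConfig(seed=0))
panel = model.select_genes(EliminationConfig(rounds=2, seed=0)).gene_panel
results = model.fit(gene_panel=panel)        # fit + cross-validate + calibrate
print(results.summary())

query, truth, _ = simulate_query(
    SimulationConfig(**{**cfg.__dict__, "cells_per_state": 40, "seed": 3}), cfg)
annotation = results.predict(query)
print(annotation.summarize()["percentages"])
```

prints (abridged):

```
Cell-state classifier (one-vs-rest linear SVM)
====================================================
states:        5
gene panel:    100 genes
C:             0.01
class weights: balanced
max_iter:      1000
calibrated:    True
CV weighted F1 (5-fold): 0.9975 (folds: 1.0000, 1.0000, 1.0000, 0.9875, 1.0000)
...
{'low': 0.0, 'medium': 2.0, 'high': 98.0}
```

i.e. the model separates the five synthetic states almost perfectly in
cross-validation, and 98% of the in-distribution query cells are annotated in
the high-certainty bin. `results.explain(query)` then lists, per state, the
genes with the largest positive mean attribution — on synthetic data these are
the planted markers.

The same workflow is available from the shell:

```bash
cellstate simulate --preset atlas15 --seed 7 --out data/
cellstate select-features --reference data/matrix.mtx --labels data/labels.tsv \
    --rounds 4 --retain-frac 0.5 --seed 7 --out sel/
cellstate train --reference data/matrix.mtx --labels data/labels.tsv \
    --panel sel/panel.txt --seed 7 --out model/
cellstate predict --model model/model.bundle --query data/matrix.mtx --out pred.tsv
cellstate run --config pipeline.toml --seed 7 --out out/   # end-to-end
```

Supported matrix formats: Matrix Market triplets with `features.tsv` /
`barcodes.tsv` sidecars (genes × cells on disk, CellRanger convention; use
`--cells-rows` otherwise), dense TSV/CSV (cells × genes), and `.h5ad`-layout
HDF5 containers.

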