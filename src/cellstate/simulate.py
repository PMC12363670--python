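"""Synthetic multi-state scRNA-seq atlas and query generator.

Counts follow a negative binomial whose mean for gene ``g`` in cell ``i`` is

    mu[i, g] = baseline_mean[g] * F^{1[g is a marker of state(i)]} * depth[i]

with baseline means drawn log-normal(0, 1), per-cell depth log-normal
(0, library_size_sigma), marker fold change ``F`` (default 8) on disjoint
per-state marker sets, and NB inverse-dispersion ``theta`` (variance
``mu + mu^2 / theta``). Queries reuse the atlas generative model and can add
a per-gene multiplicative batch shift and novel states with fresh marker
sets never seen in training — the synthetic analogue of annotating external
datasets and immature organoid populations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, ReferenceAtlas


@dataclass
class SimulationConfig:
    """Parameters of the negative-binomial atlas generator."""

    n_states: int = 15
    cells_per_state: int | list[int] = 200
    n_genes: int = 2000
    markers_per_state: int = 30
    marker_fold_change: float = 8.0
    dispersion: float = 2.0  # NB inverse-dispersion theta
    library_size_sigma: float = 0.3
    batch_shift_sigma: float = 0.0
    novel_states: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.marker_fold_change <= 1:
            raise ValidationError("marker_fold_change must exceed 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.markers_per_state < 0 or self.novel_states < 0:
            raise ValidationError("negative counts in config")
        total_states = self.n_states + self.novel_states
        if self.markers_per_state * total_states > self.n_genes:
            raise ValidationError(
                f"cannot allocate {self.markers_per_state} disjoint markers for "
                f"{total_states} states among {self.n_genes} genes"
            )

    def state_sizes(self) -> list[int]:
        if isinstance(self.cells_per_state, int):
            return [self.cells_per_state] * self.n_states
        sizes = list(self.cells_per_state)
        if len(sizes) != self.n_states:
            raise ValidationError(
                f"cells_per_state has {len(sizes)} entries for {self.n_states} states"
            )
        return sizes


def preset_atlas15(seed: int = 0, cells_per_state: int = 200) -> SimulationConfig:
    """A 15-state atlas with one rare state at ~0.5% frequency, exercising
    balanced class weights the way a rare neural-crest-like state does in a
    real tissue atlas."""
    sizes = [cells_per_state] * 14
    rare = max(5, round(0.005 * sum(sizes) / 0.995))
    return SimulationConfig(
        n_states=15, cells_per_state=sizes + [rare], seed=seed
    )


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n - 1)))
    return np.array([f"g{i:0{width}d}" for i in range(n)], dtype=object)


def _state_names(n: int, prefix: str = "S") -> list[str]:
    width = max(2, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _allocate_markers(
    rng: np.random.Generator, n_genes: int, states: list[str], per_state: int
) -> dict[str, np.ndarray]:
    pool = rng.permutation(n_genes)
    return {
        s: np.sort(pool[i * per_state:(i + 1) * per_state])
        for i, s in enumerate(states)
    }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _simulate_counts(
    rng: np.random.Generator,
    baseline: np.ndarray,
    labels: list[str],
    marker_map: dict[str, np.ndarray],
    cfg: SimulationConfig,
    gene_factor: np.ndarray | None = None,
) -> np.ndarray:
    n_cells, n_genes = len(labels), len(baseline)
    depth = rng.lognormal(0.0, cfg.library_size_sigma, size=n_cells)
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    base = baseline if gene_factor is None else baseline * gene_factor
    for i, lab in enumerate(labels):
        mu = base.copy()
        markers = marker_map.get(lab)
        if markers is not None and markers.size:
            mu[markers] *= cfg.marker_fold_change
        counts[i] = _nb_draw(rng, mu * depth[i], cfg.dispersion)
    return counts


def simulate_atlas(cfg: SimulationConfig) -> tuple[ReferenceAtlas, pd.DataFrame]:
    """Generate a labeled reference atlas plus its ground-truth marker map.

    Deterministic given ``cfg.seed``. The marker map records every planted
    (state, gene) pair along with the gene's baseline mean.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    states = _state_names(cfg.n_states)
    baseline = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    marker_map = _allocate_markers(rng, cfg.n_genes, states, cfg.markers_per_state)
    sizes = cfg.state_sizes()
    labels = [s for s, n in zip(states, sizes) for _ in range(n)]
    counts = _simulate_counts(rng, baseline, labels, marker_map, cfg)
    cells = np.array([f"cell{i:06d}" for i in range(len(labels))], dtype=object)
    matrix = ExpressionMatrix(counts, cells, genes, "raw_counts")
    marker_rows = [
        {"state": s, "gene": str(genes[g]), "baseline_mean": float(baseline[g])}
        for s in states
        for g in marker_map[s]
    ]
    markers = pd.DataFrame(marker_rows, columns=["state", "gene", "baseline_mean"])
    return ReferenceAtlas(matrix, np.array(labels, dtype=object)), markers


def simulate_query(
    cfg: SimulationConfig,
    atlas_cfg: SimulationConfig | None = None,
    permute_genes: bool = False,
) -> tuple[ExpressionMatrix, np.ndarray, pd.DataFrame]:
    """Draw a query from the atlas generative model.

    ``atlas_cfg`` pins the trained states (defaults to ``cfg``); the query's
    own ``cfg`` controls batch shift (per-gene multiplicative log-normal
    factor with sigma ``batch_shift_sigma``), the number of novel states
    (each of the query's per-state size, with fresh disjoint marker sets),
    and the query seed. Returns the raw-count matrix, the hidden true labels
    (evaluation only), and the full marker map including novel states.
    """
    if atlas_cfg is None:
        atlas_cfg = cfg
    # regenerate the atlas's gene universe deterministically
    atlas_rng = np.random.default_rng(atlas_cfg.seed)
    genes = _gene_ids(atlas_cfg.n_genes)
    states = _state_names(atlas_cfg.n_states)
    baseline = atlas_rng.lognormal(0.0, 1.0, size=atlas_cfg.n_genes)
    marker_map = _allocate_markers(
        atlas_rng, atlas_cfg.n_genes, states, atlas_cfg.markers_per_state
    )

    rng = np.random.default_rng(cfg.seed + 2**20)  # distinct stream from the atlas
    draw_cfg = replace(cfg, n_genes=atlas_cfg.n_genes,
                       markers_per_state=atlas_cfg.markers_per_state)
    if cfg.novel_states:
        taken = np.concatenate(list(marker_map.values())) if marker_map else np.array([], int)
        free = np.setdiff1d(np.arange(atlas_cfg.n_genes), taken)
        need = cfg.novel_states * atlas_cfg.markers_per_state
        if need > free.size:
            raise ValidationError(
                f"not enough unclaimed genes ({free.size}) for {cfg.novel_states} "
                f"novel states of {atlas_cfg.markers_per_state} markers"
            )
        pool = rng.permutation(free)
        novel_names = _state_names(cfg.novel_states, prefix="novel")
        for i, s in enumerate(novel_names):
            lo = i * atlas_cfg.markers_per_state
            marker_map[s] = np.sort(pool[lo:lo + atlas_cfg.markers_per_state])
        states = states + novel_names

    sizes = cfg.state_sizes()
    per_state = sizes[0] if sizes else 0
    labels = [s for s, n in zip(states[: cfg.n_states], sizes) for _ in range(n)]
    labels += [s for s in states[len(_state_names(atlas_cfg.n_states)):]
               for _ in range(per_state)]
    gene_factor = None
    if cfg.batch_shift_sigma > 0:
        gene_factor = rng.lognormal(0.0, cfg.batch_shift_sigma, size=atlas_cfg.n_genes)
    counts = _simulate_counts(rng, baseline, labels, marker_map, draw_cfg, gene_factor)
    cells = np.array([f"query{i:06d}" for i in range(len(labels))], dtype=object)
    gene_order = genes
    if permute_genes:
        perm = rng.permutation(len(genes))
        counts = counts[:, perm]
        gene_order = genes[perm]
    matrix = ExpressionMatrix(counts, cells, gene_order, "raw_counts")
    marker_rows = [
        {"state": s, "gene": str(genes[g]), "baseline_mean": float(baseline[g])}
        for s in states
        for g in marker_map[s]
    ]
    markers = pd.DataFrame(marker_rows, columns=["state", "gene", "baseline_mean"])
    return matrix, np.array(labels, dtype=object), markers
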