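"""Shapley-driven recursive feature elimination.

Each round fits an interim one-vs-rest linear SVM on the surviving genes,
scores every gene by its aggregate absolute Shapley attribution over a seeded
background subsample of reference cells, and retains the top
``ceil(retain_fraction * m)`` genes. All genes enter round 1 — HVG status is
an annotation, not a filter, so informative non-HVGs can survive into the
final panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .attribution import importance_linear
from .errors import CellStateWarning, ValidationError
from .io import ExpressionMatrix

DEFAULT_ROUNDS = 4
DEFAULT_RETAIN_FRACTION = 0.5
DEFAULT_BACKGROUND_SIZE = 1000


@dataclass
class EliminationConfig:
    """Elimination schedule: after each of ``rounds`` rounds the surviving
    gene count is ``ceil(retain_fraction * previous)``."""

    rounds: int = DEFAULT_ROUNDS
    retain_fraction: float = DEFAULT_RETAIN_FRACTION
    background_size: int = DEFAULT_BACKGROUND_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValidationError("rounds must be non-negative")
        if not 0 < self.retain_fraction <= 1:
            raise ValidationError("retain_fraction must be in (0, 1]")
        if self.background_size < 1:
            raise ValidationError("background_size must be positive")


def retention_schedule(n_genes: int, rounds: int, retain_fraction: float) -> list[int]:
    """Gene counts after each round: the iterated ``ceil(f * m)`` recurrence."""
    counts, m = [], n_genes
    for _ in range(rounds):
        m = math.ceil(retain_fraction * m)
        counts.append(m)
    return counts


@dataclass
class SelectionResult:
    """Final gene panel plus the per-round elimination report."""

    gene_panel: np.ndarray
    rounds: list[dict] = field(default_factory=list)
    n_hvg: int | None = None
    n_non_hvg: int | None = None

    def report_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rounds, columns=["round", "genes_in", "genes_out"])


def recursive_elimination(
    X_std: ExpressionMatrix,
    labels,
    cfg: EliminationConfig,
    model_cfg=None,
    hvg_flag=None,
) -> SelectionResult:
    """Run the multi-round elimination on a standardized reference matrix.

    Parameters
    ----------
    X_std : standardized reference matrix (cells x genes)
    labels : per-cell state labels (>= 2 distinct states required)
    model_cfg : hyperparameters for the interim fits; rounds reuse the final
        model's hyperparameters rather than re-tuning per round.
    hvg_flag : optional per-gene HVG annotation used only to report the
        HVG / non-HVG composition of the final panel.

    Ties on equal importance break lexicographically by gene ID, and the
    subsample is drawn from a generator seeded by ``cfg.seed``, so the
    selected panel is a deterministic function of (data, config).
    """
    from .model import ModelConfig, fit_ovr_linear_svm

    if model_cfg is None:
        model_cfg = ModelConfig()
    labels = np.asarray(labels, dtype=object)
    classes = np.unique(labels.astype(str))
    if len(classes) < 2:
        raise ValidationError("recursive elimination requires at least 2 classes")
    if X_std.layer_tag != "standardized":
        raise ValidationError("recursive_elimination expects the standardized layer")

    rng = np.random.default_rng(cfg.seed)
    current = np.arange(X_std.n_genes)
    gene_ids = X_std.gene_ids
    rows: list[dict] = []

    for r in range(1, cfg.rounds + 1):
        m = len(current)
        keep_n = math.ceil(cfg.retain_fraction * m)
        if keep_n < len(classes):
            warnings.warn(
                f"round {r}: retaining {keep_n} genes would fall below the "
                f"{len(classes)} classes; stopping early with {m} genes",
                CellStateWarning,
                stacklevel=2,
            )
            break
        Xr = X_std.values[:, current]
        coef, _, _ = fit_ovr_linear_svm(Xr, labels, model_cfg)
        n = X_std.n_cells
        if n > cfg.background_size:
            sub = np.sort(rng.choice(n, size=cfg.background_size, replace=False))
            Xb = Xr[sub]
        else:
            Xb = Xr
        Xb = np.asarray(Xb.todense()) if sp.issparse(Xb) else Xb
        mu = Xb.mean(axis=0)
        scores = importance_linear(coef, Xb, mu)
        order = sorted(
            range(m), key=lambda i: (-scores[i], str(gene_ids[current[i]]))
        )
        kept_local = np.sort(np.array(order[:keep_n]))  # original-order stability
        current = current[kept_local]
        rows.append({"round": r, "genes_in": m, "genes_out": keep_n})

    panel = gene_ids[current]
    n_hvg = n_non = None
    if hvg_flag is not None:
        hvg_flag = np.asarray(hvg_flag, dtype=bool)
        n_hvg = int(hvg_flag[current].sum())
        n_non = int(len(current) - n_hvg)
    return SelectionResult(gene_panel=panel, rounds=rows, n_hvg=n_hvg, n_non_hvg=n_non)
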