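"""Exact Shapley attributions for linear decision functions.

For a linear one-vs-rest decision function ``f_k(x) = w_k . x + b_k`` the
Shapley value of gene ``g`` relative to a background expectation ``mu`` has
the closed form

    phi[cell, g, k] = w[k, g] * (x[cell, g] - mu[g])

with per-class base value ``b_k + w_k . mu``, so that for every cell and
class ``base_value + sum_g phi`` recovers the decision score exactly
(the efficiency property). No sampling or approximation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError


@dataclass
class AttributionMatrix:
    """Per-cell, per-gene, per-class attributions plus per-class base values.

    ``phi`` has shape (cells, genes, classes); ``base_value`` has shape
    (classes,) and is the class decision score at the background mean.
    """

    phi: np.ndarray
    base_value: np.ndarray
    gene_ids: np.ndarray
    classes: np.ndarray

    def decision_scores(self) -> np.ndarray:
        """Reconstruct cells x classes decision scores via efficiency."""
        return self.base_value[None, :] + self.phi.sum(axis=1)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=np.float64)


def shap_linear(
    weights: np.ndarray,
    intercepts: np.ndarray,
    X,
    background_mean: np.ndarray,
    gene_ids=None,
    classes=None,
) -> AttributionMatrix:
    """Exact linear-model Shapley attributions.

    Parameters
    ----------
    weights : (classes, genes) one-vs-rest weight matrix
    intercepts : (classes,) decision-function intercepts
    X : (cells, genes) feature matrix sharing the weights' gene order
    background_mean : (genes,) per-gene background expectation
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    intercepts = np.atleast_1d(np.asarray(intercepts, dtype=np.float64))
    background_mean = np.asarray(background_mean, dtype=np.float64)
    Xd = _dense(X)
    k, g = weights.shape
    if Xd.shape[1] != g:
        raise ValidationError(f"X has {Xd.shape[1]} genes but weights have {g}")
    if background_mean.shape != (g,):
        raise ValidationError("background_mean length does not match gene count")
    if intercepts.shape != (k,):
        raise ValidationError("intercepts length does not match class count")
    centered = Xd - background_mean[None, :]
    # (cells, genes, classes)
    phi = centered[:, :, None] * weights.T[None, :, :]
    base = intercepts + weights @ background_mean
    if gene_ids is None:
        gene_ids = np.arange(g)
    if classes is None:
        classes = np.arange(k)
    return AttributionMatrix(
        phi=phi,
        base_value=base,
        gene_ids=np.asarray(gene_ids, dtype=object),
        classes=np.asarray(classes, dtype=object),
    )


def aggregate_importance(att: AttributionMatrix) -> np.ndarray:
    """Per-gene importance: sum over classes of the mean absolute attribution
    across cells. Non-negative and deterministic for fixed input."""
    if att.phi.shape[0] < 1:
        raise ValidationError("aggregate_importance requires at least one cell")
    return np.abs(att.phi).mean(axis=0).sum(axis=1)


def importance_linear(weights: np.ndarray, X, background_mean: np.ndarray) -> np.ndarray:
    """Memory-light equivalent of ``aggregate_importance(shap_linear(...))``.

    Because |phi| = |w| * |x - mu| factorizes for a linear model, the score
    reduces to ``sum_k |w[k, g]| * mean_c |x[c, g] - mu[g]`` without
    materializing the (cells, genes, classes) tensor.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    Xd = _dense(X)
    mean_abs_dev = np.abs(Xd - np.asarray(background_mean)[None, :]).mean(axis=0)
    return np.abs(weights).sum(axis=0) * mean_abs_dev
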