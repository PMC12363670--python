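"""Count normalization, HVG flagging, gene-space harmonization, scaling.

Query data are always brought into the model's feature space by the fixed
order ``normalize -> harmonize -> standardize``, where standardization uses
the *reference* per-gene statistics so that the classifier sees one
consistent feature space regardless of query batch structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import CellStateWarning, ValidationError
from .io import ExpressionMatrix

DEFAULT_TARGET_SUM = 1e4
DEFAULT_N_TOP_HVG = 2000
DEFAULT_MAX_MISSING = 0.5
DEFAULT_CLIP = 10.0


@dataclass
class GeneStats:
    """Per-gene mean/std of the reference's normalized layer + HVG flags.

    Genes with zero standard deviation carry no information for a linear
    classifier and are left at 0 by :func:`standardize`.
    """

    gene_ids: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    hvg_flag: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        self.hvg_flag = np.asarray(self.hvg_flag, dtype=bool)
        n = len(self.gene_ids)
        if not (len(self.mean) == len(self.std) == len(self.hvg_flag) == n):
            raise ValidationError("GeneStats fields have inconsistent lengths")
        if self.std.size and self.std.min() < 0:
            raise ValidationError("negative standard deviation")

    def subset(self, gene_ids) -> "GeneStats":
        """Restrict to ``gene_ids`` (must all be present), preserving their order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = np.array([index[g] for g in gene_ids])
        except KeyError as exc:
            raise ValidationError(f"gene {exc.args[0]!r} not in GeneStats") from exc
        return GeneStats(
            np.asarray(gene_ids, dtype=object),
            self.mean[idx], self.std[idx], self.hvg_flag[idx],
        )


def normalize_counts(
    m: ExpressionMatrix, target_sum: float = DEFAULT_TARGET_SUM
) -> ExpressionMatrix:
    """Library-size normalize to ``target_sum`` per cell, then ln(1+x).

    Cells with zero total counts are left all-zero; a single warning reports
    how many such cells were seen.
    """
    if m.layer_tag != "raw_counts":
        raise ValidationError(f"normalize_counts expects raw_counts, got {m.layer_tag}")
    if target_sum <= 0:
        raise ValidationError("target_sum must be positive")
    X = m.values
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        totals = X.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} cells with zero total counts left all-zero",
            CellStateWarning,
            stacklevel=2,
        )
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals, dtype=np.float64),
                      where=totals > 0)
    if sp.issparse(X):
        out = sp.diags(scale) @ X
        out.data = np.log1p(out.data)
        out = out.tocsr()
    else:
        out = np.log1p(X * scale[:, None])
    return ExpressionMatrix(out, m.cell_ids, m.gene_ids, "normalized")


def _dispersion(m: ExpressionMatrix) -> np.ndarray:
    """Variance/mean of the normalized layer per gene; NaN where mean == 0."""
    X = m.values
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = (X ** 2).mean(axis=0)
    var = np.maximum(sq - mean ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    return disp


def flag_hvgs(m: ExpressionMatrix, n_top: int = DEFAULT_N_TOP_HVG) -> np.ndarray:
    """Flag the ``n_top`` most dispersed genes (variance/mean, mean > 0).

    Ties are broken lexicographically by gene ID so the flag set is
    platform-independent. Genes with zero mean are never flagged.
    """
    if m.layer_tag != "normalized":
        raise ValidationError("flag_hvgs expects the normalized layer")
    if m.n_cells < 2:
        raise ValidationError("flag_hvgs requires at least 2 cells")
    if n_top < 0:
        raise ValidationError("n_top must be non-negative")
    flags = np.zeros(m.n_genes, dtype=bool)
    if n_top == 0:
        return flags
    if n_top > m.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds the {m.n_genes} genes present; flagging all",
            CellStateWarning,
            stacklevel=2,
        )
        n_top = m.n_genes
    disp = _dispersion(m)
    eligible = np.where(~np.isnan(disp))[0]
    order = sorted(eligible, key=lambda i: (-disp[i], str(m.gene_ids[i])))
    flags[order[:n_top]] = True
    return flags


def compute_gene_stats(
    m: ExpressionMatrix, n_top_hvg: int = DEFAULT_N_TOP_HVG
) -> GeneStats:
    """Per-gene mean/std (population std, ddof=0) of the normalized layer,
    plus the HVG annotation."""
    if m.layer_tag != "normalized":
        raise ValidationError("compute_gene_stats expects the normalized layer")
    X = m.values
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = (X ** 2).mean(axis=0)
    std = np.sqrt(np.maximum(sq - mean ** 2, 0.0))
    return GeneStats(m.gene_ids, mean, std, flag_hvgs(m, n_top_hvg))


def harmonize_genes(
    query: ExpressionMatrix,
    reference_genes,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> tuple[ExpressionMatrix, dict]:
    """Reindex ``query`` columns to ``reference_genes`` order.

    Genes absent from the query are zero-filled; extra query genes are
    dropped. Returns the harmonized matrix and a report with the missing-gene
    fraction. Refuses when that fraction exceeds ``max_missing``.
    """
    reference_genes = np.asarray(reference_genes, dtype=object)
    index = {g: i for i, g in enumerate(query.gene_ids)}
    positions = np.array([index.get(g, -1) for g in reference_genes])
    missing = positions < 0
    frac = float(missing.mean()) if len(reference_genes) else 0.0
    report = {
        "n_reference_genes": int(len(reference_genes)),
        "n_missing": int(missing.sum()),
        "missing_fraction": frac,
    }
    if frac > max_missing:
        raise ValidationError(
            f"{report['n_missing']}/{report['n_reference_genes']} reference genes "
            f"({100 * frac:.1f}%) are absent from the query, above the "
            f"{100 * max_missing:.0f}% limit; check that query gene identifiers "
            "use the same symbol convention as the reference"
        )
    X = query.values
    if sp.issparse(X):
        cols = [
            X[:, positions[j]] if positions[j] >= 0
            else sp.csr_matrix((X.shape[0], 1))
            for j in range(len(reference_genes))
        ]
        out = sp.hstack(cols, format="csr") if cols else sp.csr_matrix((X.shape[0], 0))
    else:
        out = np.zeros((X.shape[0], len(reference_genes)), dtype=np.float64)
        present = positions >= 0
        out[:, present] = X[:, positions[present]]
    return ExpressionMatrix(out, query.cell_ids, reference_genes, query.layer_tag), report


def standardize(
    m: ExpressionMatrix, stats: GeneStats, clip: float = DEFAULT_CLIP
) -> ExpressionMatrix:
    """Per-gene z-score with the *reference* statistics, clipped to ±clip.

    Zero-std genes are non-informative and output 0.
    """
    if m.layer_tag != "normalized":
        raise ValidationError("standardize expects the normalized layer")
    if not np.array_equal(m.gene_ids, stats.gene_ids):
        raise ValidationError("gene order mismatch between matrix and GeneStats")
    X = m.to_dense()
    denom = np.where(stats.std > 0, stats.std, 1.0)
    Z = (X - stats.mean) / denom
    Z[:, stats.std == 0] = 0.0
    np.clip(Z, -clip, clip, out=Z)
    return ExpressionMatrix(Z, m.cell_ids, m.gene_ids, "standardized")
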