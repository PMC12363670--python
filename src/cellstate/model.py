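"""Multiclass linear max-margin cell-state classifier.

The public surface follows the Model/Results convention: build a
:class:`CellStateModel` from a labeled :class:`~cellstate.io.ReferenceAtlas`,
optionally run :meth:`~CellStateModel.select_genes` /
:meth:`~CellStateModel.tune`, then :meth:`~CellStateModel.fit` to obtain a
:class:`CellStateResults` carrying the one-vs-rest weights, per-class Platt
calibrators, reference gene statistics and a training report
(cross-validated weighted F1, per-class precision/recall/F1, reliability
curves). ``CellStateResults.predict`` annotates query datasets.

Defaults (C = 0.01, balanced class weights, 1,000 max iterations, 5 folds)
suit sparse, high-dimensional scRNA-seq references with strongly imbalanced
states; the classifier is a hinge-loss, L2-regularized linear SVM decomposed
one-vs-rest so that each state owns a decision score its calibrator can map
to a probability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import f1_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import CellStateWarning, ConfigError, ValidationError
from .io import ExpressionMatrix, ReferenceAtlas, save_model
from .preprocess import (
    DEFAULT_N_TOP_HVG,
    DEFAULT_TARGET_SUM,
    GeneStats,
    compute_gene_stats,
    normalize_counts,
    standardize,
)

DEFAULT_TUNING_GRID = {
    "C": [0.001, 0.01, 0.1, 1.0],
    "class_weight": ["balanced"],
    "max_iter": [1000],
}


@dataclass
class ModelConfig:
    """Hyperparameters of the linear SVM and its evaluation protocol."""

    C: float = 0.01
    class_weight: str = "balanced"  # or "uniform"
    max_iter: int = 1000
    folds: int = 5
    tuning_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TUNING_GRID.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError("regularization strength C must be > 0")
        if self.class_weight not in ("balanced", "uniform"):
            raise ConfigError("class_weight must be 'balanced' or 'uniform'")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "class_weight": self.class_weight,
            "max_iter": self.max_iter,
            "folds": self.folds,
            "tuning_grid": self.tuning_grid,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def weighted_f1(y_true, y_pred) -> float:
    """Class-size-weighted mean of per-class F1 scores.

    F1 of a class with undefined precision and recall counts as 0.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValidationError("weighted_f1 requires at least one item")
    return float(f1_score(y_true.astype(str), y_pred.astype(str),
                          average="weighted", zero_division=0))


def expected_calibration_error(confidence, correct, n_bins: int = 10) -> float:
    """ECE with equal-width confidence bins on [0, 1]: the support-weighted
    mean absolute gap between within-bin accuracy and mean confidence."""
    confidence = np.asarray(confidence, dtype=np.float64)
    correct = np.asarray(correct, dtype=np.float64)
    if confidence.size == 0:
        raise ValidationError("expected_calibration_error requires data")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(confidence, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            ece += mask.mean() * abs(correct[mask].mean() - confidence[mask].mean())
    return float(ece)


# ---------------------------------------------------------------------------
# low-level one-vs-rest SVM fit
# ---------------------------------------------------------------------------

def fit_ovr_linear_svm(X, y, cfg: ModelConfig):
    """Fit one-vs-rest hinge-loss linear SVMs.

    Returns ``(coef, intercept, convergence_warnings)`` with one weight row
    and intercept per class in lexicographic class order; for two classes the
    single discriminant is expanded into symmetric per-class rows so every
    class owns a decision score.
    """
    y = np.asarray(y, dtype=str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("fit requires at least 2 classes")
    cw = "balanced" if cfg.class_weight == "balanced" else None
    svc = LinearSVC(
        C=cfg.C,
        loss="hinge",
        class_weight=cw,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    conv: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        svc.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            msg = f"linear SVM did not converge within max_iter={cfg.max_iter}"
            conv.append(msg)
            warnings.warn(msg, CellStateWarning, stacklevel=2)
    coef = np.asarray(svc.coef_, dtype=np.float64)
    intercept = np.asarray(svc.intercept_, dtype=np.float64)
    if len(classes) == 2:  # expand the single binary discriminant
        coef = np.vstack([-coef, coef])
        intercept = np.concatenate([-intercept, intercept])
    return coef, intercept, conv


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------

def _platt_fit(scores: np.ndarray, y01: np.ndarray) -> tuple[float, float, bool]:
    """Fit P(y=1|s) = sigmoid(-(A*s + B)) on out-of-fold scores.

    Uses Platt's smoothed targets and constrains A <= 0 so the map is
    non-decreasing in the score. Returns (A, B, fallback_used); the fallback
    (A=-1, B=0) is an identity-like logistic on the raw score, used when the
    scores are all identical and carry no ranking information.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y01 = np.asarray(y01, dtype=np.float64)
    if np.allclose(scores, scores[0]):
        return -1.0, 0.0, True
    n_pos = float(y01.sum())
    n_neg = float(len(y01) - n_pos)
    t = np.where(y01 > 0, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(params):
        a, b = params
        z = a * scores + b
        nll = np.sum(t * np.logaddexp(0.0, z) + (1.0 - t) * np.logaddexp(0.0, -z))
        dz = expit(z) - (1.0 - t)
        return nll, np.array([np.dot(dz, scores), dz.sum()])

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(
        objective,
        x0=np.array([-1.0, b0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 0.0), (None, None)],
    )
    a, b = res.x
    return float(a), float(b), False


def platt_apply(scores, a, b) -> np.ndarray:
    return expit(-(np.asarray(scores) * a + b))


def _reliability_curve(prob: np.ndarray, y01: np.ndarray, n_bins: int = 10) -> list[dict]:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(prob, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin_lo": float(edges[b]),
            "bin_hi": float(edges[b + 1]),
            "count": int(mask.sum()),
            "mean_prob": float(prob[mask].mean()) if mask.any() else float("nan"),
            "frac_positive": float(y01[mask].mean()) if mask.any() else float("nan"),
        })
    return rows


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class CellStateResults:
    """A fitted (and possibly calibrated) cell-state classifier.

    Carries everything needed to annotate a query: the selected gene panel,
    the reference per-gene statistics used to standardize queries, per-class
    linear weights/intercepts, per-class Platt calibrators, and the training
    report. Uncalibrated results refuse to predict.
    """

    classes: np.ndarray
    gene_panel: np.ndarray
    gene_stats: GeneStats
    coef: np.ndarray
    intercept: np.ndarray
    config: ModelConfig
    calib_a: np.ndarray | None = None
    calib_b: np.ndarray | None = None
    training_report: dict = field(default_factory=dict)

    @property
    def calibrated(self) -> bool:
        return self.calib_a is not None and self.calib_b is not None

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        return X @ self.coef.T + self.intercept

    def calibrated_probabilities(self, scores: np.ndarray) -> np.ndarray:
        """Per-class calibrated probabilities, renormalized to sum to 1."""
        if not self.calibrated:
            from .errors import UncalibratedModelError

            raise UncalibratedModelError(
                "uncalibrated model: run CellStateModel.calibrate (or fit with "
                "calibrate=True) before predicting"
            )
        raw = platt_apply(scores, self.calib_a[None, :], self.calib_b[None, :])
        totals = raw.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return raw / totals

    # -- user-facing conveniences ------------------------------------------
    def predict(self, query: ExpressionMatrix, **kw):
        from .annotate import predict as _predict

        return _predict(self, query, **kw)

    def explain(self, query: ExpressionMatrix, records=None, n_top: int = 10):
        from .annotate import top_explainable_genes

        return top_explainable_genes(self, query, records=records, n_top=n_top)

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "CellStateResults":
        from .io import load_model

        return load_model(path)

    def summary(self) -> str:
        """Plain-text summary of the fitted classifier."""
        rep = self.training_report
        lines = [
            "Cell-state classifier (one-vs-rest linear SVM)",
            "=" * 52,
            f"states:        {len(self.classes)}",
            f"gene panel:    {len(self.gene_panel)} genes",
            f"C:             {self.config.C}",
            f"class weights: {self.config.class_weight}",
            f"max_iter:      {self.config.max_iter}",
            f"calibrated:    {self.calibrated}",
        ]
        cv = rep.get("cv")
        if cv:
            lines.append(
                f"CV weighted F1 ({self.config.folds}-fold): "
                f"{cv['weighted_f1']:.4f} "
                f"(folds: {', '.join(f'{s:.4f}' for s in cv['fold_scores'])})"
            )
            per = cv.get("per_class", {})
            if per:
                lines.append("-" * 52)
                lines.append(f"{'state':<20}{'prec':>8}{'recall':>8}{'F1':>8}{'n':>7}")
                for c in self.classes:
                    row = per.get(str(c))
                    if row:
                        lines.append(
                            f"{str(c):<20}{row['precision']:>8.3f}"
                            f"{row['recall']:>8.3f}{row['f1']:>8.3f}{row['support']:>7d}"
                        )
        if rep.get("convergence_warnings"):
            lines.append(f"convergence warnings: {len(rep['convergence_warnings'])}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class CellStateModel:
    """Cell-state classification model bound to a labeled reference atlas.

    Parameters
    ----------
    atlas : ReferenceAtlas with raw counts.
    config : ModelConfig; defaults are the selected hyperparameters
        (C=0.01, balanced, max_iter=1000, 5 folds).
    target_sum, n_top_hvg : preprocessing knobs (library-size target for
        normalization; HVG annotation size).

    The normalized layer and reference gene statistics are computed once and
    shared by feature selection, fitting, tuning, cross-validation and
    calibration.
    """

    def __init__(
        self,
        atlas: ReferenceAtlas,
        config: ModelConfig | None = None,
        target_sum: float = DEFAULT_TARGET_SUM,
        n_top_hvg: int = DEFAULT_N_TOP_HVG,
    ) -> None:
        self.atlas = atlas
        self.config = config or ModelConfig()
        self.target_sum = target_sum
        self.n_top_hvg = min(n_top_hvg, atlas.matrix.n_genes)
        self._normalized: ExpressionMatrix | None = None
        self._gene_stats: GeneStats | None = None

    @classmethod
    def from_files(cls, matrix_path, labels_path, format: str = "mtx", **kw):
        from .io import read_atlas

        return cls(read_atlas(matrix_path, labels_path, format=format), **kw)

    # -- cached layers ------------------------------------------------------
    @property
    def normalized(self) -> ExpressionMatrix:
        if self._normalized is None:
            self._normalized = normalize_counts(self.atlas.matrix, self.target_sum)
        return self._normalized

    @property
    def gene_stats(self) -> GeneStats:
        if self._gene_stats is None:
            self._gene_stats = compute_gene_stats(self.normalized, self.n_top_hvg)
        return self._gene_stats

    def _design(self, gene_panel=None) -> tuple[np.ndarray, GeneStats, np.ndarray]:
        if gene_panel is None:
            gene_panel = self.atlas.matrix.gene_ids
        gene_panel = np.asarray(gene_panel, dtype=object)
        stats = self.gene_stats.subset(gene_panel)
        index = {g: i for i, g in enumerate(self.normalized.gene_ids)}
        cols = np.array([index[g] for g in gene_panel])
        sub = ExpressionMatrix(
            self.normalized.values[:, cols],
            self.normalized.cell_ids,
            gene_panel,
            "normalized",
        )
        X = standardize(sub, stats).to_dense()
        return X, stats, gene_panel

    def _check_class_sizes(self) -> None:
        counts = self.atlas.class_counts()
        small = {c: n for c, n in counts.items() if n < self.config.folds}
        if small:
            raise ValidationError(
                "classes with fewer cells than folds: "
                + ", ".join(f"{c} ({n})" for c, n in small.items())
                + f"; use a smaller K than {self.config.folds}"
            )

    # -- feature selection --------------------------------------------------
    def select_genes(self, elim_cfg=None):
        """Run Shapley-driven recursive feature elimination on the atlas."""
        from .selection import EliminationConfig, recursive_elimination

        X, stats, panel = self._design(None)
        std = ExpressionMatrix(X, self.atlas.matrix.cell_ids, panel, "standardized")
        return recursive_elimination(
            std,
            self.atlas.labels,
            elim_cfg or EliminationConfig(seed=self.config.seed),
            self.config,
            hvg_flag=stats.hvg_flag,
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        gene_panel=None,
        calibrate: bool = True,
        cross_validate: bool = True,
    ) -> CellStateResults:
        """Fit the one-vs-rest SVM on the (standardized) reference.

        With ``calibrate=True`` the per-class Platt calibrators are fitted on
        out-of-fold decision scores from an internal stratified split; with
        ``cross_validate=True`` the training report includes per-fold and
        aggregate weighted F1 plus per-class precision/recall/F1.
        """
        if self.atlas.n_states < 2:
            raise ValidationError("fit requires at least 2 classes")
        self._check_class_sizes()
        X, stats, panel = self._design(gene_panel)
        y = self.atlas.labels
        coef, intercept, conv = fit_ovr_linear_svm(X, y, self.config)
        report: dict = {
            "n_cells": int(X.shape[0]),
            "n_genes": int(X.shape[1]),
            "class_counts": self.atlas.class_counts(),
            "convergence_warnings": conv,
        }
        results = CellStateResults(
            classes=self.atlas.label_vocabulary.copy(),
            gene_panel=panel,
            gene_stats=stats,
            coef=coef,
            intercept=intercept,
            config=self.config,
            training_report=report,
        )
        if cross_validate:
            report["cv"] = self.cross_validate(gene_panel=panel, _design=(X, y))
        if calibrate:
            results = self.calibrate(results, _design=(X, y))
        return results

    # -- evaluation ---------------------------------------------------------
    def cross_validate(self, gene_panel=None, _design=None) -> dict:
        """Stratified K-fold cross-validation scored by weighted F1."""
        self._check_class_sizes()
        if _design is None:
            X, _, _ = self._design(gene_panel)
            y = self.atlas.labels
        else:
            X, y = _design
        y = np.asarray(y, dtype=str)
        skf = StratifiedKFold(
            n_splits=self.config.folds, shuffle=True, random_state=self.config.seed
        )
        fold_scores: list[float] = []
        oof_pred = np.empty_like(y)
        for train_idx, test_idx in skf.split(X, y):
            coef, intercept, _ = fit_ovr_linear_svm(X[train_idx], y[train_idx], self.config)
            classes = np.unique(y[train_idx])
            scores = X[test_idx] @ coef.T + intercept
            pred = classes[np.argmax(scores, axis=1)]
            oof_pred[test_idx] = pred
            fold_scores.append(weighted_f1(y[test_idx], pred))
        prec, rec, f1c, supp = precision_recall_fscore_support(
            y, oof_pred, labels=np.unique(y), zero_division=0
        )
        per_class = {
            str(c): {
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "support": int(s),
            }
            for c, p, r, f, s in zip(np.unique(y), prec, rec, f1c, supp)
        }
        return {
            "fold_scores": [float(s) for s in fold_scores],
            "weighted_f1": float(np.mean(fold_scores)),
            "per_class": per_class,
        }

    def tune(self, gene_panel=None, grid: dict | None = None):
        """Exhaustive grid search scored by cross-validated weighted F1.

        Ties break toward smaller C (stronger regularization), then balanced
        class weights, then smaller max_iter. Returns (best ModelConfig,
        grid table as a DataFrame).
        """
        grid = dict(grid or self.config.tuning_grid)
        cs = list(grid.get("C", [self.config.C]))
        cws = list(grid.get("class_weight", [self.config.class_weight]))
        iters = list(grid.get("max_iter", [self.config.max_iter]))
        if not cs or not cws or not iters:
            raise ConfigError("tuning grid has an empty axis")
        for c in cs:
            if c <= 0:
                raise ConfigError(f"invalid C={c} in tuning grid: must be > 0")
        for cw in cws:
            if cw not in ("balanced", "uniform"):
                raise ConfigError(f"invalid class_weight {cw!r} in tuning grid")
        for it in iters:
            if it < 1:
                raise ConfigError(f"invalid max_iter={it} in tuning grid")
        X, _, panel = self._design(gene_panel)
        y = self.atlas.labels
        rows = []
        for c, cw, it in itertools.product(cs, cws, iters):
            cfg = replace(self.config, C=c, class_weight=cw, max_iter=it)
            sub = CellStateModel.__new__(CellStateModel)
            sub.__dict__ = {**self.__dict__, "config": cfg}
            cv = sub.cross_validate(_design=(X, y))
            rows.append({
                "C": c, "class_weight": cw, "max_iter": it,
                "weighted_f1": cv["weighted_f1"],
            })
        table = pd.DataFrame(rows)
        best_row = min(
            rows,
            key=lambda r: (
                -r["weighted_f1"], r["C"],
                0 if r["class_weight"] == "balanced" else 1,
                r["max_iter"],
            ),
        )
        best = replace(
            self.config,
            C=best_row["C"],
            class_weight=best_row["class_weight"],
            max_iter=best_row["max_iter"],
        )
        return best, table

    # -- calibration --------------------------------------------------------
    def calibrate(self, results: CellStateResults, _design=None) -> CellStateResults:
        """Fit per-class Platt calibrators on out-of-fold decision scores.

        Uses an internal stratified K-fold split (seeded independently of the
        evaluation folds) so no calibrator ever sees scores produced by a
        model trained on the same cells. Classes whose out-of-fold scores are
        all identical get an identity-like fallback map and a warning.
        """
        if _design is None:
            X, _, _ = self._design(results.gene_panel)
            y = self.atlas.labels
        else:
            X, y = _design
        y = np.asarray(y, dtype=str)
        classes = results.classes.astype(str)
        skf = StratifiedKFold(
            n_splits=self.config.folds, shuffle=True,
            random_state=self.config.seed + 101,
        )
        oof = np.zeros((len(y), len(classes)))
        for train_idx, test_idx in skf.split(X, y):
            coef, intercept, _ = fit_ovr_linear_svm(X[train_idx], y[train_idx], self.config)
            oof[test_idx] = X[test_idx] @ coef.T + intercept
        calib_a = np.zeros(len(classes))
        calib_b = np.zeros(len(classes))
        reliability: dict[str, list[dict]] = {}
        fallback: list[str] = []
        for k, c in enumerate(classes):
            y01 = (y == c).astype(float)
            a, b, used_fallback = _platt_fit(oof[:, k], y01)
            calib_a[k], calib_b[k] = a, b
            if used_fallback:
                fallback.append(c)
            reliability[c] = _reliability_curve(platt_apply(oof[:, k], a, b), y01)
        if fallback:
            warnings.warn(
                "identity-like calibration fallback for classes with constant "
                "scores: " + ", ".join(fallback),
                CellStateWarning,
                stacklevel=2,
            )
        report = dict(results.training_report)
        report["calibration"] = {
            "reliability": reliability,
            "fallback_classes": fallback,
        }
        return replace(
            results, calib_a=calib_a, calib_b=calib_b, training_report=report
        )
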