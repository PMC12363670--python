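"""Query annotation: labels, calibrated certainty scores, explanations.

A query of raw counts is pushed through ``normalize -> harmonize ->
standardize`` (with the model's reference statistics), scored by the
one-vs-rest discriminants, mapped through the per-class Platt calibrators
and renormalized. The certainty score of a cell is its maximum renormalized
probability, binned low (< 0.3), medium ([0.3, 0.7)) or high (>= 0.7);
distribution-shifted or reference-absent populations surface as depressed
certainty rather than a hard "unknown" call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CellStateWarning, ValidationError
from .io import ExpressionMatrix
from .preprocess import (
    DEFAULT_MAX_MISSING,
    DEFAULT_TARGET_SUM,
    harmonize_genes,
    normalize_counts,
    standardize,
)

TAU_LOW = 0.3
TAU_HIGH = 0.7
BINS = ("low", "medium", "high")


@dataclass(frozen=True)
class CertaintyThresholds:
    """Certainty bin edges. Boundary convention: low = [0, tau_low),
    medium = [tau_low, tau_high), high = [tau_high, 1]."""

    tau_low: float = TAU_LOW
    tau_high: float = TAU_HIGH

    def __post_init__(self) -> None:
        if not 0 <= self.tau_low < self.tau_high <= 1:
            raise ValidationError("need 0 <= tau_low < tau_high <= 1")


def bin_certainty(s: float, thresholds: CertaintyThresholds | None = None) -> str:
    """Assign a certainty score to its bin."""
    t = thresholds or CertaintyThresholds()
    if not 0 <= s <= 1:
        raise ValidationError(f"certainty score {s} outside [0, 1]")
    if s < t.tau_low:
        return "low"
    if s < t.tau_high:
        return "medium"
    return "high"


@dataclass
class PredictionRecord:
    """Annotation of one query cell."""

    cell_id: str
    predicted_label: str
    probabilities: np.ndarray  # over the model's label vocabulary
    certainty: float
    bin: str


@dataclass
class AnnotationResult:
    """Per-cell prediction records plus the harmonization report."""

    records: list[PredictionRecord]
    classes: np.ndarray
    harmonization: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cls = self.classes.astype(str)
        rows = {
            "cell_id": [r.cell_id for r in self.records],
            "predicted_label": [r.predicted_label for r in self.records],
            "certainty": [r.certainty for r in self.records],
            "bin": [r.bin for r in self.records],
        }
        probs = np.array([r.probabilities for r in self.records])
        for j, c in enumerate(cls):
            rows[f"p_{c}"] = probs[:, j]
        return pd.DataFrame(rows)

    def summarize(self, thresholds: CertaintyThresholds | None = None) -> dict:
        return summarize(self.records, thresholds)


def predict(
    results,
    query: ExpressionMatrix,
    thresholds: CertaintyThresholds | None = None,
    target_sum: float = DEFAULT_TARGET_SUM,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> AnnotationResult:
    """Annotate a raw-count query with a calibrated model.

    Argmax ties break toward the lexicographically smallest state (the label
    vocabulary is sorted, and the first maximum wins).
    """
    from .errors import UncalibratedModelError

    if not results.calibrated:
        raise UncalibratedModelError(
            "uncalibrated model: run CellStateModel.calibrate before predict"
        )
    if query.layer_tag != "raw_counts":
        raise ValidationError("predict expects a raw-count query")
    t = thresholds or CertaintyThresholds()
    norm = normalize_counts(query, target_sum)
    harm, harm_report = harmonize_genes(norm, results.gene_panel, max_missing)
    std = standardize(harm, results.gene_stats)
    scores = results.decision_function(std.values)
    probs = results.calibrated_probabilities(scores)
    pred_idx = np.argmax(probs, axis=1)
    classes = results.classes.astype(str)
    records = []
    for i, cid in enumerate(query.cell_ids):
        certainty = float(probs[i, pred_idx[i]])
        records.append(
            PredictionRecord(
                cell_id=str(cid),
                predicted_label=classes[pred_idx[i]],
                probabilities=probs[i].copy(),
                certainty=certainty,
                bin=bin_certainty(certainty, t),
            )
        )
    return AnnotationResult(records=records, classes=results.classes,
                            harmonization=harm_report)


def summarize(records, thresholds: CertaintyThresholds | None = None) -> dict:
    """Per-bin counts/percentages, per-state median certainty, and the
    cumulative-density table used for certainty plots."""
    if not records:
        raise ValidationError("summarize requires at least one record")
    t = thresholds or CertaintyThresholds()
    certainties = np.array([r.certainty for r in records])
    bins = [bin_certainty(float(s), t) for s in certainties]
    counts = {b: bins.count(b) for b in BINS}
    total = len(records)
    percentages = {b: 100.0 * counts[b] / total for b in BINS}
    per_state: dict[str, dict] = {}
    for state in sorted({r.predicted_label for r in records}):
        vals = np.array([r.certainty for r in records if r.predicted_label == state])
        per_state[state] = {
            "n_cells": int(len(vals)),
            "median_certainty": float(np.median(vals)),
        }
    order = np.sort(certainties)
    cumulative = {
        "certainty": order.tolist(),
        "cumulative_fraction": ((np.arange(total) + 1) / total).tolist(),
    }
    return {
        "n_cells": total,
        "counts": counts,
        "percentages": percentages,
        "per_state": per_state,
        "cumulative_density": cumulative,
    }


@dataclass
class ExplanationTable:
    """Per predicted state, the genes with the largest positive mean Shapley
    attribution over the cells predicted as that state."""

    per_state: dict[str, list[tuple[str, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": s, "rank": i + 1, "gene": g, "mean_attribution": v}
            for s, pairs in self.per_state.items()
            for i, (g, v) in enumerate(pairs)
        ]
        return pd.DataFrame(rows, columns=["state", "rank", "gene", "mean_attribution"])


def top_explainable_genes(
    results,
    query: ExpressionMatrix,
    records=None,
    n_top: int = 10,
    target_sum: float = DEFAULT_TARGET_SUM,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> ExplanationTable:
    """Rank genes driving each state's predictions on *this* query.

    For state ``c`` the attribution of gene ``g`` in a predicted-c cell is
    ``w[c, g] * (x_std[g] - 0)`` — the background is the reference mean,
    which is the origin of the standardized space. Only strictly positive
    mean attributions are kept, ordered non-increasing, truncated to
    ``n_top``. States with no predicted cells are omitted with a warning.
    """
    if records is None:
        records = predict(results, query, target_sum=target_sum,
                          max_missing=max_missing).records
    if n_top < 0:
        raise ValidationError("n_top must be non-negative")
    norm = normalize_counts(query, target_sum)
    harm, _ = harmonize_genes(norm, results.gene_panel, max_missing)
    X = standardize(harm, results.gene_stats).to_dense()
    id_index = {str(c): i for i, c in enumerate(query.cell_ids)}
    try:
        rows = [id_index[r.cell_id] for r in records]
    except KeyError as exc:
        raise ValidationError(
            f"record cell {exc.args[0]!r} not present in the query"
        ) from exc
    X = X[rows]
    pred = np.array([r.predicted_label for r in records], dtype=object)
    classes = results.classes.astype(str)
    genes = results.gene_panel.astype(str)
    table: dict[str, list[tuple[str, float]]] = {}
    empty = []
    for k, c in enumerate(classes):
        mask = pred == c
        if not mask.any():
            empty.append(c)
            continue
        mean_phi = results.coef[k] * X[mask].mean(axis=0)
        order = sorted(
            np.where(mean_phi > 0)[0],
            key=lambda j: (-mean_phi[j], genes[j]),
        )[:n_top]
        table[c] = [(genes[j], float(mean_phi[j])) for j in order]
    if empty:
        warnings.warn(
            "states with no predicted cells omitted from the explanation "
            "table: " + ", ".join(empty),
            CellStateWarning,
            stacklevel=2,
        )
    return ExplanationTable(per_state=table)
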