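"""Fitting, tuning, cross-validation, calibration, and the weighted F1 metric."""

import numpy as np
import pytest

from cellstate import (
    CellStateModel,
    CellStateWarning,
    ConfigError,
    ModelConfig,
    SimulationConfig,
    ValidationError,
    simulate_atlas,
    weighted_f1,
)
from cellstate.model import fit_ovr_linear_svm, platt_apply


def brute_force_weighted_f1(y_true, y_pred):
    """Confusion-matrix oracle: sum_c (n_c / N) * F1_c."""
    y_true, y_pred = list(y_true), list(y_pred)
    total = 0.0
    for c in set(y_true):
        tp = sum(t == c and p == c for t, p in zip(y_true, y_pred))
        fp = sum(t != c and p == c for t, p in zip(y_true, y_pred))
        fn = sum(t == c and p != c for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += (y_true.count(c) / len(y_true)) * f1
    return total


class TestWeightedF1:
    def test_perfect(self):
        assert weighted_f1(["A", "B", "A"], ["A", "B", "A"]) == 1.0

    def test_disjoint(self):
        assert weighted_f1(["A", "A", "B"], ["B", "B", "A"]) == 0.0

    def test_hand_computed_mixed_case(self):
        # F1_A = 2/3, F1_B = 2/3, weights 2/3 and 1/3 -> 2/3
        assert weighted_f1(["A", "A", "B"], ["A", "B", "B"]) == pytest.approx(2 / 3)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            weighted_f1([], [])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        labels = np.array(["A", "B", "C", "D"])
        for _ in range(200):
            n = rng.integers(1, 30)
            y_true = labels[rng.integers(0, 4, size=n)]
            y_pred = labels[rng.integers(0, 4, size=n)]
            assert weighted_f1(y_true, y_pred) == pytest.approx(
                brute_force_weighted_f1(y_true, y_pred), abs=1e-12
            )


class TestModelConfig:
    def test_defaults_are_selected_hyperparameters(self):
        cfg = ModelConfig()
        assert cfg.C == 0.01
        assert cfg.class_weight == "balanced"
        assert cfg.max_iter == 1000
        assert cfg.folds == 5

    @pytest.mark.parametrize("kw", [
        {"C": 0.0}, {"C": -1.0}, {"class_weight": "weird"},
        {"max_iter": 0}, {"folds": 1},
    ])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigError):
            ModelConfig(**kw)


def _blobs(n_per, centers, spread, seed):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, (c, n) in enumerate(zip(centers, n_per)):
        X.append(rng.normal(loc=c, scale=spread, size=(n, len(c))))
        y += [f"blob{i}"] * n
    return np.vstack(X), np.array(y)


class TestFit:
    def test_separable_blobs_training_accuracy_one(self):
        X, y = _blobs([20, 20], [(-3.0, -3.0), (3.0, 3.0)], 0.3, seed=0)
        coef, intercept, _ = fit_ovr_linear_svm(X, y, ModelConfig(C=1.0, seed=0))
        pred = np.unique(y)[np.argmax(X @ coef.T + intercept, axis=1)]
        assert (pred == y).mean() == 1.0

    def test_single_class_error(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValidationError, match="2 classes"):
            fit_ovr_linear_svm(X, ["A"] * 5, ModelConfig())

    def test_balanced_weights_help_minority_recall(self):
        # 95:5 imbalance with overlap: balanced weighting must not do worse
        # on the minority class than uniform weighting
        X, y = _blobs([190, 10], [(-1.0, 0.0), (1.0, 0.0)], 1.0, seed=0)
        recalls = {}
        for cw in ("balanced", "uniform"):
            coef, intercept, _ = fit_ovr_linear_svm(
                X, y, ModelConfig(C=1.0, class_weight=cw, seed=0)
            )
            pred = np.unique(y)[np.argmax(X @ coef.T + intercept, axis=1)]
            minority = y == "blob1"
            recalls[cw] = (pred[minority] == "blob1").mean()
        assert recalls["balanced"] >= recalls["uniform"]

    def test_class_smaller_than_folds_named_in_error(self):
        cfg = SimulationConfig(n_states=2, cells_per_state=[10, 3],
                               n_genes=30, markers_per_state=3, seed=0)
        atlas, _ = simulate_atlas(cfg)
        model = CellStateModel(atlas, ModelConfig(folds=5))
        with pytest.raises(ValidationError, match="S01"):
            model.fit()

    def test_fit_is_deterministic(self, model):
        a = model.fit(cross_validate=False)
        b = model.fit(cross_validate=False)
        assert np.array_equal(a.coef, b.coef)
        assert np.array_equal(a.intercept, b.intercept)
        assert np.array_equal(a.calib_a, b.calib_a)
        assert np.array_equal(a.calib_b, b.calib_b)


class TestCrossValidate:
    def test_separable_atlas_near_perfect_score(self, model, marker_map):
        # restrict to the planted marker genes: states are then cleanly
        # separable and the stratified CV score should be essentially perfect
        cv = model.cross_validate(gene_panel=np.sort(marker_map["gene"].unique()))
        assert cv["weighted_f1"] >= 0.98
        assert len(cv["fold_scores"]) == 5
        assert set(cv["per_class"]) == {"S00", "S01", "S02", "S03", "S04"}

    def test_permuted_labels_score_at_chance(self):
        cfg = SimulationConfig(n_states=10, cells_per_state=30, n_genes=100,
                               markers_per_state=4, seed=0)
        atlas, _ = simulate_atlas(cfg)
        rng = np.random.default_rng(0)
        atlas.labels = atlas.labels[rng.permutation(len(atlas.labels))]
        score = CellStateModel(atlas, ModelConfig(seed=0)).cross_validate()
        assert score["weighted_f1"] <= 0.2

    def test_k_exceeding_smallest_class_errors(self, atlas):
        model = CellStateModel(atlas, ModelConfig(folds=81))
        with pytest.raises(ValidationError, match="smaller K"):
            model.cross_validate()


class TestTune:
    def test_single_point_grid_equals_cross_validate(self, model):
        best, table = model.tune(grid={"C": [0.01]})
        assert len(table) == 1
        assert best.C == 0.01
        assert table.iloc[0]["weighted_f1"] == pytest.approx(
            model.cross_validate()["weighted_f1"]
        )

    def test_easy_data_scores_close_and_tie_breaks_to_smaller_c(self, model):
        best, table = model.tune(grid={"C": [0.01, 1.0]})
        scores = table["weighted_f1"].to_numpy()
        assert abs(scores[0] - scores[1]) < 0.05
        if scores[0] == scores[1]:
            assert best.C == 0.01

    def test_invalid_grid_rejected_before_any_fit(self, model):
        with pytest.raises(ConfigError, match="C=-1"):
            model.tune(grid={"C": [-1.0]})


class TestCalibrate:
    def test_probabilities_sum_to_one(self, fitted, atlas):
        ann = fitted.predict(atlas.matrix)
        probs = np.array([r.probabilities for r in ann.records])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_true_class_probability_high_on_separated_data(self, fitted, atlas):
        ann = fitted.predict(atlas.matrix)
        idx = {c: i for i, c in enumerate(fitted.classes.astype(str))}
        p_true = np.array([
            r.probabilities[idx[str(lab)]]
            for r, lab in zip(ann.records, atlas.labels)
        ])
        assert p_true.mean() >= 0.9

    def test_calibrators_are_monotone(self, fitted):
        assert np.all(fitted.calib_a <= 0)
        s = np.linspace(-5, 5, 101)
        for a, b in zip(fitted.calib_a, fitted.calib_b):
            p = platt_apply(s, a, b)
            assert np.all(np.diff(p) >= 0)

    def test_reliability_curves_stored_per_class(self, fitted):
        rel = fitted.training_report["calibration"]["reliability"]
        assert set(rel) == set(fitted.classes.astype(str))
        assert all(len(rows) == 10 for rows in rel.values())

    def test_constant_score_class_gets_fallback_with_warning(self):
        # constant counts -> zero-variance genes -> all-zero standardized
        # layer -> identical decision scores for every cell
        from cellstate import ExpressionMatrix, ReferenceAtlas

        counts = np.full((40, 10), 5.0)
        atlas = ReferenceAtlas(
            ExpressionMatrix(counts, [f"c{i}" for i in range(40)],
                             [f"g{j}" for j in range(10)]),
            np.array(["A", "B"] * 20, dtype=object),
        )
        model = CellStateModel(atlas, ModelConfig(seed=0), n_top_hvg=10)
        with pytest.warns(CellStateWarning, match="fallback"):
            res = model.fit(cross_validate=False)
        assert res.training_report["calibration"]["fallback_classes"]


def test_summary_reports_cv_and_classes(fitted):
    text = fitted.summary()
    assert "weighted F1" in text
    assert "S00" in text and "S04" in text
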