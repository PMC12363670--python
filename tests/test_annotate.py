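"""Prediction records, certainty binning, summaries, and explanations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellstate import (
    CellStateWarning,
    CertaintyThresholds,
    ExpressionMatrix,
    PredictionRecord,
    SimulationConfig,
    ValidationError,
    bin_certainty,
    simulate_query,
    summarize,
    top_explainable_genes,
)


class TestBinCertainty:
    @pytest.mark.parametrize("score,expected", [
        (0.75, "high"),      # above the 0.7 threshold
        (0.5, "medium"),     # between 0.3 and 0.7
        (0.29, "low"),
        (0.30, "medium"),    # boundary: medium is [0.3, 0.7)
        (0.70, "high"),      # boundary: high is [0.7, 1]
        (0.0, "low"),
        (1.0, "high"),
    ])
    def test_bin_assignment(self, score, expected):
        assert bin_certainty(score) == expected

    @pytest.mark.parametrize("score", [-0.1, 1.1])
    def test_out_of_range_errors(self, score):
        with pytest.raises(ValidationError, match="outside"):
            bin_certainty(score)

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            CertaintyThresholds(tau_low=0.7, tau_high=0.3)

    @given(s=st.floats(0, 1), t=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_score(self, s, t):
        order = {"low": 0, "medium": 1, "high": 2}
        lo, hi = sorted((s, t))
        assert order[bin_certainty(lo)] <= order[bin_certainty(hi)]

    @given(s=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_raising_tau_high_never_promotes_to_high(self, s):
        loose = bin_certainty(s, CertaintyThresholds(0.3, 0.7))
        strict = bin_certainty(s, CertaintyThresholds(0.3, 0.8))
        if strict == "high":
            assert loose == "high"


@pytest.fixture(scope="module")
def shift_fixture():
    from cellstate import CellStateModel, ModelConfig, simulate_atlas

    cfg = SimulationConfig(n_states=5, cells_per_state=100, n_genes=1000,
                           markers_per_state=8, marker_fold_change=6.0, seed=7)
    atlas, _ = simulate_atlas(cfg)
    results = CellStateModel(atlas, ModelConfig(seed=0)).fit(cross_validate=False)
    return results, cfg


def _records(certainties, labels=None):
    labels = labels or ["A"] * len(certainties)
    return [
        PredictionRecord(cell_id=f"c{i}", predicted_label=lab,
                         probabilities=np.array([]), certainty=c,
                         bin=bin_certainty(c))
        for i, (c, lab) in enumerate(zip(certainties, labels))
    ]


class TestSummarize:
    def test_direct_count_example(self):
        s = summarize(_records([0.1, 0.2] + [0.5] * 4 + [0.8] * 4))
        assert s["counts"] == {"low": 2, "medium": 4, "high": 4}
        assert s["percentages"] == {"low": 20.0, "medium": 40.0, "high": 40.0}

    def test_counts_sum_to_total_and_percentages_to_100(self):
        rng = np.random.default_rng(1)
        s = summarize(_records(rng.uniform(0, 1, 37)))
        assert sum(s["counts"].values()) == 37
        assert sum(s["percentages"].values()) == pytest.approx(100.0)

    def test_single_state_single_row(self):
        s = summarize(_records([0.9, 0.8], labels=["X", "X"]))
        assert list(s["per_state"]) == ["X"]
        assert s["per_state"]["X"]["n_cells"] == 2

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            summarize([])

    def test_oracle_recount_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            scores = rng.uniform(0, 1, rng.integers(1, 40))
            s = summarize(_records(scores))
            # brute-force recount
            low = sum(x < 0.3 for x in scores)
            med = sum(0.3 <= x < 0.7 for x in scores)
            high = sum(x >= 0.7 for x in scores)
            assert s["counts"] == {"low": low, "medium": med, "high": high}
            for b, n in (("low", low), ("medium", med), ("high", high)):
                assert s["percentages"][b] == pytest.approx(100 * n / len(scores))


class TestPredict:
    def test_duplicated_reference_cell_gives_identical_records(self, fitted, atlas):
        row = atlas.matrix.to_dense()[0]
        query = ExpressionMatrix(
            np.tile(row, (5, 1)), [f"q{i}" for i in range(5)],
            atlas.matrix.gene_ids, "raw_counts",
        )
        ann = fitted.predict(query)
        first = ann.records[0]
        for r in ann.records[1:]:
            assert r.predicted_label == first.predicted_label
            assert r.certainty == first.certainty
            assert np.array_equal(r.probabilities, first.probabilities)

    def test_gene_permutation_invariance(self, fitted, atlas):
        dense = atlas.matrix.to_dense()[:20]
        cells = [f"q{i}" for i in range(20)]
        base = ExpressionMatrix(dense, cells, atlas.matrix.gene_ids, "raw_counts")
        perm = np.random.default_rng(4).permutation(dense.shape[1])
        shuffled = ExpressionMatrix(
            dense[:, perm], cells, atlas.matrix.gene_ids[perm], "raw_counts"
        )
        a, b = fitted.predict(base), fitted.predict(shuffled)
        for ra, rb in zip(a.records, b.records):
            assert ra.predicted_label == rb.predicted_label
            assert ra.certainty == rb.certainty

    def test_cell_order_invariance(self, fitted, atlas):
        dense = atlas.matrix.to_dense()[:20]
        cells = np.array([f"q{i}" for i in range(20)], dtype=object)
        base = ExpressionMatrix(dense, cells, atlas.matrix.gene_ids, "raw_counts")
        order = np.random.default_rng(5).permutation(20)
        reordered = ExpressionMatrix(dense[order], cells[order],
                                     atlas.matrix.gene_ids, "raw_counts")
        by_id_a = {r.cell_id: r for r in fitted.predict(base).records}
        by_id_b = {r.cell_id: r for r in fitted.predict(reordered).records}
        assert by_id_a.keys() == by_id_b.keys()
        for cid in by_id_a:
            assert by_id_a[cid].certainty == by_id_b[cid].certainty

    def test_in_distribution_query_mostly_high_bin(self, fitted, atlas_cfg):
        query, _, _ = simulate_query(
            SimulationConfig(**{**atlas_cfg.__dict__, "cells_per_state": 60,
                                "seed": 2}),
            atlas_cfg,
        )
        s = fitted.predict(query).summarize()
        assert s["percentages"]["high"] >= 90.0

    def test_novel_state_scores_lower_certainty(self, fitted, atlas_cfg):
        query, truth, _ = simulate_query(
            SimulationConfig(**{**atlas_cfg.__dict__, "cells_per_state": 50,
                                "novel_states": 1, "seed": 11}),
            atlas_cfg,
        )
        cert = np.array([r.certainty for r in fitted.predict(query).records])
        novel = np.array([str(t).startswith("novel") for t in truth])
        assert np.median(cert[novel]) < np.median(cert[~novel])

    @pytest.mark.parametrize("seed", [100, 101, 102, 103, 104])
    def test_batch_shift_depresses_certainty(self, shift_fixture, seed):
        """In-distribution queries score higher mean certainty than queries
        under a multiplicative per-gene batch shift (log-normal sigma 0.5).

        Uses a moderately separated atlas so certainties sit below the
        saturation ceiling where the shift effect would vanish into noise.
        """
        results, cfg = shift_fixture
        kw = {**cfg.__dict__, "cells_per_state": 200, "seed": seed}
        clean, _, _ = simulate_query(SimulationConfig(**kw), cfg)
        shifted, _, _ = simulate_query(
            SimulationConfig(**{**kw, "batch_shift_sigma": 0.5}), cfg
        )
        mean_clean = np.mean([r.certainty for r in results.predict(clean).records])
        mean_shift = np.mean([r.certainty for r in results.predict(shifted).records])
        assert mean_clean > mean_shift

    def test_requires_raw_counts(self, fitted):
        m = ExpressionMatrix(np.ones((2, 3)), ["a", "b"], ["g1", "g2", "g3"],
                             "normalized")
        with pytest.raises(ValidationError, match="raw-count"):
            fitted.predict(m)


class TestExplanations:
    def test_planted_markers_dominate_top10(self, fitted, atlas, marker_map):
        table = fitted.explain(atlas.matrix, n_top=10)
        for state, pairs in table.per_state.items():
            planted = set(marker_map[marker_map.state == str(state)]["gene"])
            top = {g for g, _ in pairs}
            assert len(top & planted) >= 5

    def test_values_positive_and_non_increasing(self, fitted, atlas):
        table = fitted.explain(atlas.matrix, n_top=10)
        for pairs in table.per_state.values():
            vals = [v for _, v in pairs]
            assert all(v > 0 for v in vals)
            assert vals == sorted(vals, reverse=True)

    def test_n_top_zero_empty_lists(self, fitted, atlas):
        table = fitted.explain(atlas.matrix, n_top=0)
        assert all(pairs == [] for pairs in table.per_state.values())

    def test_zero_weight_gene_never_appears(self, fitted, atlas):
        import copy

        res = copy.deepcopy(fitted)
        res.coef[:, 0] = 0.0  # silence the first panel gene everywhere
        gene = str(res.gene_panel[0])
        table = res.explain(atlas.matrix, n_top=400)
        for pairs in table.per_state.values():
            assert gene not in {g for g, _ in pairs}

    def test_unpredicted_state_omitted_with_warning(self, fitted, atlas):
        records = fitted.predict(atlas.matrix).records
        only_s00 = [r for r in records if r.predicted_label == "S00"]
        with pytest.warns(CellStateWarning, match="no predicted cells"):
            table = top_explainable_genes(fitted, atlas.matrix, records=only_s00)
        assert set(table.per_state) == {"S00"}
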