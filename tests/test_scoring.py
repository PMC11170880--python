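"""Score combination, labeling, ATAC gating and evaluation."""

import numpy as np
import pandas as pd
import pytest

import caracal as cc

from conftest import make_count_matrix


class TestCombineUpDown:
    def test_direct_arithmetic(self):
        assert cc.combine_up_down(0.9, 0.1) == pytest.approx(1.8, abs=1e-15)

    def test_bounds(self):
        assert cc.combine_up_down(0.0, 1.0) == 0.0
        assert cc.combine_up_down(1.0, 0.0) == 2.0

    def test_elementwise_and_monotonicity(self):
        rng = np.random.default_rng(0)
        up = rng.uniform(0, 1, size=(50, 3))
        down = rng.uniform(0, 1, size=(50, 3))
        out = cc.combine_up_down(up, down)
        assert out.shape == (50, 3)
        assert np.all((out >= 0) & (out <= 2))
        # strictly increasing in up, strictly decreasing in down
        assert np.all(cc.combine_up_down(np.minimum(up + 0.001, 1), down) >= out)
        assert np.all(cc.combine_up_down(up, np.minimum(down + 0.001, 1)) <= out)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        up=st.floats(min_value=0, max_value=1),
        down=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_hold_for_any_valid_inputs(self, up, down):
        out = cc.combine_up_down(up, down)
        assert 0 <= out <= 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cc.combine_up_down(1.2, 0.5)
        with pytest.raises(ValueError):
            cc.combine_up_down(0.5, -0.1)


class TestScoreCellTypes:
    def test_both_directions_combined(self, tiny):
        norm = cc.log_normalize(tiny.activity)
        params = cc.VamParameters(n_permutations=200, seed=1)
        scores = cc.score_cell_types(norm, tiny.planted, params)
        assert scores.cell_types == ["type0", "type1"]
        np.testing.assert_allclose(scores.combined, scores.up + 1 - scores.down)
        assert np.all((scores.combined >= 0) & (scores.combined <= 2))
        assert scores.up_only == set()

    def test_missing_down_set_pins_down_score(self, tiny):
        norm = cc.log_normalize(tiny.activity)
        up_only_sets = [s for s in tiny.planted if s.direction == "up"]
        params = cc.VamParameters(n_permutations=200, seed=1)
        scores = cc.score_cell_types(norm, up_only_sets, params)
        np.testing.assert_array_equal(scores.down, 1.0)
        np.testing.assert_allclose(scores.combined, scores.up)
        assert scores.up_only == {"type0", "type1"}

    def test_missing_up_set_is_error(self, tiny):
        norm = cc.log_normalize(tiny.activity)
        down_only = [s for s in tiny.planted if s.direction == "down"]
        with pytest.raises(ValueError, match="up-regulated"):
            cc.score_cell_types(norm, down_only, cc.VamParameters(n_permutations=200))

    def test_deterministic_under_seed(self, tiny):
        norm = cc.log_normalize(tiny.activity)
        params = cc.VamParameters(n_permutations=150, seed=3)
        a = cc.score_cell_types(norm, tiny.planted, params)
        b = cc.score_cell_types(norm, tiny.planted, params)
        np.testing.assert_array_equal(a.combined, b.combined)


def scores_from(combined, cell_types):
    combined = np.asarray(combined, dtype=float)
    return cc.CellTypeScores(
        barcodes=[f"c{i}" for i in range(combined.shape[0])],
        cell_types=list(cell_types),
        up=np.clip(combined, 0, 1),
        down=np.zeros_like(combined),
        combined=combined,
    )


class TestAssignLabels:
    def test_argmax_with_margin(self):
        labels = cc.assign_labels(scores_from([[1.4, 0.6]], ["T", "B"]))
        row = labels.iloc[0]
        assert (row["label"], row["margin"], row["tie"]) == ("T", pytest.approx(0.8), False)

    def test_exact_tie_prefers_lexicographic(self):
        labels = cc.assign_labels(scores_from([[1.0, 1.0]], ["T", "B"]))
        row = labels.iloc[0]
        assert row["label"] == "B"
        assert row["tie"]

    def test_min_score_threshold(self):
        labels = cc.assign_labels(scores_from([[1.1, 0.2]], ["T", "B"]), min_score=1.2)
        assert labels.iloc[0]["label"] == "unassigned"

    def test_single_type_margin_zero(self):
        labels = cc.assign_labels(scores_from([[0.7]], ["T"]))
        assert labels.iloc[0]["margin"] == 0

    def test_invariant_to_cell_type_ordering(self):
        rng = np.random.default_rng(5)
        combined = rng.uniform(0, 2, size=(40, 4))
        types = ["T", "B", "NK", "Mono"]
        ref = cc.assign_labels(scores_from(combined, types))
        order = [2, 0, 3, 1]
        out = cc.assign_labels(scores_from(combined[:, order], [types[i] for i in order]))
        assert ref["label"].tolist() == out["label"].tolist()
        np.testing.assert_allclose(ref["margin"], out["margin"])


def brute_force_integrate(rna, atac):
    out = np.zeros_like(rna)
    for j in range(rna.shape[1]):
        med = np.median(atac[:, j])
        for i in range(rna.shape[0]):
            out[i, j] = rna[i, j] if atac[i, j] > med else 0.0
    return out


class TestIntegrateScores:
    def frame(self, values, types=("T", "B")):
        values = np.asarray(values, dtype=float)
        return pd.DataFrame(
            values, index=[f"c{i}" for i in range(values.shape[0])], columns=list(types)
        )

    def test_above_median_passes_through(self):
        rna = self.frame([[0.8], [0.5], [0.2]], types=["T"])
        atac = self.frame([[0.9], [0.5], [0.1]], types=["T"])
        gated, medians = cc.integrate_scores(rna, atac)
        assert medians["T"] == 0.5
        assert gated.loc["c0", "T"] == 0.8

    def test_exactly_at_median_gates_to_zero(self):
        rna = self.frame([[0.8], [0.5], [0.2]], types=["T"])
        atac = self.frame([[0.9], [0.5], [0.1]], types=["T"])
        gated, _ = cc.integrate_scores(rna, atac)
        assert gated.loc["c1", "T"] == 0.0

    def test_zero_rna_stays_zero(self):
        rna = self.frame([[0.0], [0.0], [0.0]], types=["T"])
        atac = self.frame([[0.9], [0.5], [0.1]], types=["T"])
        gated, _ = cc.integrate_scores(rna, atac)
        assert (gated["T"] == 0).all()

    def test_matches_brute_force_and_median_property(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            rna = rng.uniform(0, 2, size=(31, 4))
            atac = rng.uniform(0, 1, size=(31, 4))
            rna_f = self.frame(rna, types=["A", "B", "C", "D"])
            atac_f = self.frame(atac, types=["A", "B", "C", "D"])
            gated, _ = cc.integrate_scores(rna_f, atac_f)
            np.testing.assert_array_equal(gated.to_numpy(), brute_force_integrate(rna, atac))
            # with distinct scores at odd n, at least ceil(n/2) cells gate to 0
            assert ((gated.to_numpy() == 0).sum(axis=0) >= 16).all()
            # gated output never exceeds the RNA input
            assert np.all(gated.to_numpy() <= rna + 1e-15)

    def test_mismatched_inputs_error(self):
        rna = self.frame(np.ones((2, 2)))
        atac = self.frame(np.ones((2, 2)), types=("T", "NK"))
        with pytest.raises(ValueError, match="cell types"):
            cc.integrate_scores(rna, atac)

    def test_alignment_by_barcode_not_position(self):
        rna = self.frame([[1.0, 0.4], [0.2, 1.3]])
        atac = self.frame([[0.9, 0.1], [0.1, 0.8]])
        reordered = atac.iloc[[1, 0]]
        a, _ = cc.integrate_scores(rna, atac)
        b, _ = cc.integrate_scores(rna, reordered)
        pd.testing.assert_frame_equal(a, b)


class TestEvaluateLabels:
    def table(self, pairs):
        return pd.DataFrame(
            [(b, l, 1.0, 0.5, False) for b, l in pairs],
            columns=["barcode", "label", "top_score", "margin", "tie"],
        )

    def test_hand_counted_agreement(self):
        pred = self.table([("c1", "A"), ("c2", "A"), ("c3", "B")])
        report = cc.evaluate_labels(pred, {"c1": "A", "c2": "B", "c3": "B"})
        assert report.agreement == pytest.approx(2 / 3)
        assert report.confusion.loc["B", "A"] == 1

    def test_identical_labelings(self):
        pred = self.table([("c1", "A"), ("c2", "B")])
        report = cc.evaluate_labels(pred, {"c1": "A", "c2": "B"})
        assert report.agreement == 1.0
        off_diagonal = report.confusion.to_numpy() - np.diag(np.diag(report.confusion))
        assert off_diagonal.sum() == 0

    def test_disjoint_vocabularies(self):
        pred = self.table([("c1", "X"), ("c2", "Y")])
        report = cc.evaluate_labels(pred, {"c1": "A", "c2": "B"})
        assert report.agreement == 0.0
        assert list(report.confusion.index) == ["A", "B", "X", "Y"]

    def test_missing_cells_excluded_and_counted(self):
        pred = self.table([("c1", "A"), ("only_pred", "A")])
        report = cc.evaluate_labels(pred, {"c1": "A", "only_truth": "B"})
        assert report.n_shared == 1
        assert report.n_only_predicted == 1
        assert report.n_only_truth == 1

    def test_zero_shared_is_error(self):
        pred = self.table([("c1", "A")])
        with pytest.raises(ValueError, match="shared"):
            cc.evaluate_labels(pred, {"other": "A"})
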