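"""Integrated gradients and connectome aggregation."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from fcage.attribution import (
    AttributionMatrix,
    edge_contribution_table,
    group_density_summary,
    integrated_gradients,
    mean_group_attribution,
    node_strength,
    trajectory_classification,
)
from fcage.autodiff import Tensor
from fcage.types import GROUP_ORDER

P = 8


class LinearModel:
    """F(x) = sum_i w_i x_i — the closed-form attribution oracle.

    The path integral of a constant gradient is exact for any step count,
    so IG must return w_i * x_i exactly.
    """

    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=float).reshape(-1, 1))
        self.spec = SimpleNamespace(task="regression", input_size=P)

    def forward(self, x):
        return x.reshape(x.shape[0], P * P) @ self.w


def _fold(raw):
    off = raw - np.diag(np.diag(raw))
    return off + off.T + np.diag(np.diag(raw))


class TestIntegratedGradients:
    def test_input_equal_baseline_gives_zero(self, rng):
        model = LinearModel(rng.standard_normal(P * P))
        x = rng.standard_normal((P, P))
        attr = integrated_gradients(model, x, baseline=x.copy(), steps=10)
        assert np.all(attr.values == 0)

    @pytest.mark.parametrize("m", [1, 3, 50])
    def test_linear_model_closed_form(self, m, rng):
        w = rng.standard_normal(P * P)
        x = rng.standard_normal((P, P))
        attr = integrated_gradients(LinearModel(w), x, steps=m)
        expected = _fold((w.reshape(P, P)) * x)
        assert np.abs(attr.values - expected).max() < 1e-8
        assert attr.total == pytest.approx(float(w @ x.ravel()), abs=1e-8)

    def test_completeness_error_shrinks_with_steps(self, toy_trained_model):
        """Riemann-sum error of the path integral decreases toward zero in m."""
        model = toy_trained_model["classification"]["model"]
        x = toy_trained_model["x_test"][0]
        errs = []
        for m in (10, 50, 300):
            attr = integrated_gradients(model, x, steps=m, auto_escalate=False)
            errs.append(abs(attr.total - (attr.f_x - attr.f_baseline)))
        delta = abs(integrated_gradients(model, x, steps=10, auto_escalate=False).f_x
                    - integrated_gradients(model, x, steps=10, auto_escalate=False).f_baseline)
        assert errs[2] <= 0.05 * delta
        assert errs[0] >= errs[1] >= errs[2]

    def test_deterministic(self, toy_trained_model):
        model = toy_trained_model["classification"]["model"]
        x = toy_trained_model["x_test"][1]
        a = integrated_gradients(model, x, steps=20)
        b = integrated_gradients(model, x, steps=20)
        assert np.array_equal(a.values, b.values)

    def test_bad_steps_rejected(self, rng):
        with pytest.raises(ValueError):
            integrated_gradients(LinearModel(np.ones(P * P)), rng.standard_normal((P, P)), steps=0)

    def test_result_symmetric(self, toy_trained_model):
        clf = toy_trained_model["classification"]["model"]
        attr = integrated_gradients(clf, toy_trained_model["x_test"][2], steps=20)
        assert np.abs(attr.values - attr.values.T).max() < 1e-12


class TestMeanGroupAttribution:
    def _attr(self, vals):
        return AttributionMatrix(values=np.asarray(vals, float), target="young")

    def test_single_subject_per_group(self, rng):
        mats = [self._attr(rng.standard_normal((3, 3))) for _ in range(4)]
        for m in mats:
            m.values = (m.values + m.values.T) / 2
        out = mean_group_attribution(mats, list(GROUP_ORDER))
        for g, m in zip(GROUP_ORDER, mats):
            assert np.array_equal(out[g].values, m.values)

    def test_identical_pair_mean_unchanged(self, rng):
        a = (lambda v: (v + v.T) / 2)(rng.standard_normal((3, 3)))
        mats = [self._attr(a), self._attr(a)] + [self._attr(np.zeros((3, 3))) for _ in range(3)]
        out = mean_group_attribution(mats, ["young", "young", "adult", "middle_old", "old"])
        assert np.array_equal(out["young"].values, a)

    def test_cancellation(self, rng):
        a = (lambda v: (v + v.T) / 2)(rng.standard_normal((3, 3)))
        mats = [self._attr(a), self._attr(-a)] + [self._attr(np.zeros((3, 3))) for _ in range(3)]
        out = mean_group_attribution(mats, ["young", "young", "adult", "middle_old", "old"])
        assert np.abs(out["young"].values).max() < 1e-15

    def test_empty_group_rejected(self, rng):
        mats = [self._attr(np.zeros((2, 2))) for _ in range(3)]
        with pytest.raises(ValueError, match="old"):
            mean_group_attribution(mats, ["young", "adult", "middle_old"])


class TestNodeStrength:
    def test_single_positive_edge(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 0.5
        ns = node_strength(m)
        assert list(ns["positive"]) == [0.5, 0.5, 0, 0]
        assert list(ns["negative"]) == [0, 0, 0, 0]

    def test_single_negative_edge(self):
        m = np.zeros((4, 4))
        m[2, 3] = m[3, 2] = -0.3
        ns = node_strength(m)
        assert list(ns["negative"]) == [0, 0, -0.3, -0.3]

    def test_signed_sum(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.2
        m[0, 2] = m[2, 0] = -0.1
        ns = node_strength(m)
        assert ns.loc[0, "net"] == pytest.approx(0.1)
        assert ns.loc[0, "positive"] == pytest.approx(0.2)
        assert ns.loc[0, "negative"] == pytest.approx(-0.1)

    def test_conservation(self, rng):
        """Total net strength counts every edge at both endpoints."""
        a = rng.standard_normal((10, 10))
        m = (a + a.T) / 2
        ns = node_strength(m)
        off = m - np.diag(np.diag(m))
        edge_sum = off[np.tril_indices(10, -1)].sum()
        assert ns["net"].sum() == pytest.approx(2 * edge_sum, abs=1e-9)

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            node_strength(rng.standard_normal((4, 4)))


class TestEdgeContributionTable:
    def _group_means(self, edges):
        """edges: {(i, j): (v_young, v_adult, v_mo, v_old)} on a 4-ROI parcel."""
        mats = [np.zeros((4, 4)) for _ in range(4)]
        for (i, j), vals in edges.items():
            for m, v in zip(mats, vals):
                m[i, j] = m[j, i] = v
        return {g: AttributionMatrix(values=m, target=g) for g, m in zip(GROUP_ORDER, mats)}

    def test_all_zero_gives_empty_table(self):
        table = edge_contribution_table(self._group_means({}))
        assert table.empty

    def test_threshold_boundary(self):
        gm = self._group_means({(1, 0): (0.19, 0.19, 0.19, 0.19), (2, 0): (0.21, 0.21, 0.21, 0.21)})
        table = edge_contribution_table(gm, threshold=0.2)
        assert len(table) == 1
        assert table.iloc[0]["roi1"] == "ROI000" and table.iloc[0]["roi2"] == "ROI002"

    def test_retained_edge_keeps_group_columns(self):
        gm = self._group_means({(1, 0): (0.61, 0.56, 0.57, 0.49)})
        table = edge_contribution_table(gm, threshold=0.2)
        assert list(table[list(GROUP_ORDER)].iloc[0]) == [0.61, 0.56, 0.57, 0.49]

    def test_unknown_roi_label_rejected(self):
        atlas = pd.DataFrame({"roi_label": ["A"], "network": ["N"], "hemisphere": ["LH"]})
        with pytest.raises(KeyError):
            edge_contribution_table(self._group_means({(1, 0): (0.5,) * 4}), atlas=atlas)

    def test_missing_group_rejected(self):
        gm = self._group_means({})
        del gm["old"]
        with pytest.raises(ValueError, match="old"):
            edge_contribution_table(gm)


class TestTrajectoryClassification:
    @pytest.mark.parametrize("values,label", [
        ((0.632, 0.551, 0.556, 0.512), "decreasing"),   # peak at young, small mid bump
        ((0.324, 0.341, 0.370, 0.364), "inverted_U"),   # peak at middle_old
        ((0.5, 0.5, 0.5, 0.5), "flat"),
        ((0.4, 0.45, 0.46, 0.41), "inverted_U"),
        ((0.6, 0.5, 0.4, 0.3), "decreasing"),
        ((0.3, 0.3, 0.31, 0.3), "flat"),
    ])
    def test_rule(self, values, label):
        assert trajectory_classification(values, tau=0.01) == label

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            trajectory_classification([1.0, 2.0, 3.0])

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError):
            trajectory_classification([0.1, np.nan, 0.2, 0.1])


class TestGroupDensitySummary:
    def test_identical_values_degenerate_stats(self):
        cells = {"NetA": {g: np.full(5, 0.4) for g in GROUP_ORDER}}
        df = group_density_summary(cells)
        row = df.iloc[0]
        assert row["sd"] == 0 and row["q1"] == row["median"] == row["q3"] == 0.4

    def test_quartiles(self):
        cells = {"NetA": {g: np.array([1.0, 2.0, 3.0, 4.0]) for g in GROUP_ORDER}}
        row = group_density_summary(cells).iloc[0]
        assert row["mean"] == 2.5 and row["median"] == 2.5

    def test_direction_delegates_to_trajectory_rule(self):
        cells = {"NetA": {g: np.full(4, v) for g, v in zip(GROUP_ORDER, (0.4, 0.45, 0.46, 0.41))}}
        df = group_density_summary(cells)
        assert set(df["direction"]) == {"inverted_U"}

    def test_empty_cell_flagged_not_fatal(self):
        cells = {"NetA": {g: np.array([1.0, 2.0]) for g in GROUP_ORDER}}
        cells["NetA"]["old"] = np.array([])
        df = group_density_summary(cells)
        assert (df["flag"] == "insufficient").sum() == 1
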