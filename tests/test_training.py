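"""Stratified protocols, the training loop, and metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcage.models import ModelSpec, build_model
from fcage.pipeline import cohort_features, run_end_to_end
from fcage.training import (
    TrainConfig,
    classification_report,
    cross_validate,
    evaluate_classification,
    evaluate_regression,
    group_index,
    stratified_split,
    train,
)
from fcage.types import GROUP_ORDER, Subject


def _subjects(group_sizes, with_sex=False):
    ages = {"young": 30, "adult": 50, "middle_old": 60, "old": 80}
    subs = []
    k = 0
    for label, n in zip(GROUP_ORDER, group_sizes):
        for i in range(n):
            sex = ("F" if i % 2 else "M") if with_sex else "NA"
            subs.append(Subject(f"s{k:04d}", ages[label], sex))
            k += 1
    return subs


class TestStratifiedSplit:
    def test_reference_group_sizes(self):
        """Group sizes 172/152/154/160 at ratio 0.2 give the expected test counts."""
        subs = _subjects((172, 152, 154, 160))
        plan = stratified_split(subs, ratio=0.2, seed=0)
        by_group = {s.subject_id: s.group for s in subs}
        counts = {g: sum(1 for i in plan.test_ids if by_group[i] == g) for g in GROUP_ORDER}
        assert counts["young"] in (34, 35)
        assert counts["adult"] in (30, 31)
        assert counts["middle_old"] in (30, 31)
        assert counts["old"] == 32
        for g, n in zip(GROUP_ORDER, (172, 152, 154, 160)):
            assert abs(counts[g] - 0.2 * n) <= 1

    def test_small_single_group(self):
        subs = [Subject(f"s{i}", 25) for i in range(10)]
        plan = stratified_split(subs, ratio=0.2, seed=1)
        assert len(plan.test_ids) == 2
        assert len(plan.train_ids) == 8

    def test_deterministic_under_seed(self):
        subs = _subjects((20, 20, 20, 20), with_sex=True)
        a = stratified_split(subs, seed=5)
        b = stratified_split(subs, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = stratified_split(subs, seed=6)
        assert a.test_ids != c.test_ids

    def test_disjoint_and_complete(self):
        subs = _subjects((25, 25, 25, 25), with_sex=True)
        plan = stratified_split(subs, seed=2)
        assert not set(plan.train_ids) & set(plan.test_ids)
        assert len(plan.train_ids) + len(plan.test_ids) == 100

    def test_sex_is_secondary_stratum(self):
        subs = _subjects((40, 40, 40, 40), with_sex=True)
        plan = stratified_split(subs, ratio=0.25, seed=3)
        sex_of = {s.subject_id: (s.group, s.sex) for s in subs}
        for g in GROUP_ORDER:
            for sex in ("F", "M"):
                n_test = sum(1 for i in plan.test_ids if sex_of[i] == (g, sex))
                assert abs(n_test - 0.25 * 20) <= 1

    def test_tiny_group_rejected(self):
        subs = _subjects((5, 5, 5, 1))
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(subs)


class TestTrainLoop:
    def test_zero_epochs_returns_initial_weights(self, small_cohort):
        mats, groups, _ = cohort_features(small_cohort)
        model = build_model(ModelSpec(input_size=16), seed=1)
        before = model.state_dict()
        model, trace = train(model, mats[:16], groups[:16], TrainConfig(epochs=0, seed=1))
        assert trace == []
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_training_loss_beats_chance_level(self, small_cohort):
        """Planted-signal cohort: cross-entropy falls below ln(4), the 4-class chance level."""
        mats, groups, _ = cohort_features(small_cohort)
        model = build_model(ModelSpec(input_size=16), seed=1)
        _, trace = train(model, mats, groups, TrainConfig(epochs=6, seed=1))
        assert trace[-1] < np.log(4)
        assert trace[-1] < trace[0]

    def test_same_seed_identical_final_weights(self, small_cohort):
        mats, groups, _ = cohort_features(small_cohort)
        runs = []
        for _ in range(2):
            model = build_model(ModelSpec(input_size=16), seed=3)
            model, _ = train(model, mats[:32], groups[:32], TrainConfig(epochs=2, seed=3))
            runs.append(model.state_dict())
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])


class TestClassificationMetrics:
    def test_perfect_predictions_score_100(self):
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        assert classification_report(y, y).accuracy == 100.0

    def test_constant_predictor_on_balanced_set_scores_25(self):
        y = np.array([0, 1, 2, 3] * 5)
        assert classification_report(np.zeros_like(y), y).accuracy == 25.0

    def test_partial_correctness_counting(self):
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        pred = np.array([0, 1, 2, 3, 0, 0, 0, 0])  # 5 of 8 correct
        assert classification_report(pred, y).accuracy == 62.5

    def test_accuracy_counting(self, toy_trained_model, small_cohort):
        model = toy_trained_model["classification"]["model"]
        x = toy_trained_model["x_test"]
        mats, groups, _ = cohort_features(small_cohort)
        y = groups[toy_trained_model["test_idx"]]
        report = evaluate_classification(model, x, y)
        assert 0 <= report.accuracy <= 100
        assert report.confusion.sum() == len(y)
        # row sums equal per-class test counts
        assert np.array_equal(report.confusion.sum(axis=1), np.bincount(y, minlength=4))
        # accuracy equals diagonal fraction
        assert report.accuracy == pytest.approx(100 * np.trace(report.confusion) / len(y))

    def test_empty_test_set_rejected(self, toy_trained_model):
        model = toy_trained_model["classification"]["model"]
        with pytest.raises(ValueError, match="empty"):
            evaluate_classification(model, np.zeros((0, 16, 16)), np.array([], dtype=int))


class TestRegressionMetrics:
    def test_exact_predictions(self):
        r = evaluate_regression(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert (r.mae, r.rmse, r.r2) == (0, 0, 1)

    def test_constant_predictor_r2_zero(self):
        r = evaluate_regression(np.array([5.0, 5.0]), np.array([0.0, 10.0]))
        assert r.mae == 5 and r.rmse == 5 and r.r2 == 0

    def test_shifted_predictions(self):
        r = evaluate_regression(np.array([2.0, 3, 4]), np.array([1.0, 2, 3]))
        assert r.mae == pytest.approx(1) and r.rmse == pytest.approx(1)
        assert r.r2 == pytest.approx(-0.5)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate_regression(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        y = rng.normal(50, 15, n)
        yhat = y + rng.normal(0, 5, n)
        if np.var(y) == 0:
            return
        r = evaluate_regression(yhat, y)
        assert r.rmse >= r.mae >= 0


class TestCrossValidate:
    def test_fold_metrics_and_mean(self, small_cohort):
        mats, groups, _ = cohort_features(small_cohort)
        spec = ModelSpec(input_size=16)
        folds, mean = cross_validate(spec, mats, groups, groups, k=3,
                                     config=TrainConfig(epochs=2, seed=1))
        assert len(folds) == 3
        assert mean.accuracy == pytest.approx(np.mean([f.accuracy for f in folds]), abs=1e-9)
        assert sum(f.n for f in folds) == len(groups)

    def test_same_seed_identical_folds(self, small_cohort):
        mats, groups, _ = cohort_features(small_cohort)
        spec = ModelSpec(input_size=16)
        cfg = TrainConfig(epochs=1, seed=4)
        a, _ = cross_validate(spec, mats, groups, groups, k=2, config=cfg)
        b, _ = cross_validate(spec, mats, groups, groups, k=2, config=cfg)
        for ra, rb in zip(a, b):
            assert ra.accuracy == rb.accuracy
            assert np.array_equal(ra.confusion, rb.confusion)

    def test_k_below_two_rejected(self, small_cohort):
        mats, groups, _ = cohort_features(small_cohort)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec(input_size=16), mats, groups, groups, k=1)


def test_attention_resnet_outperforms_plain_vgg_and_chance(recovery_runs):
    """Architecture ordering on planted-signal data: attention-augmented ResNet
    beats a plain VGG trunk on average, and both clear the 25% chance level."""
    resnet_accs, vgg_accs = [], []
    for run in recovery_runs:
        resnet_accs.append(run["result"]["classification"]["report"].accuracy)
        res = run_end_to_end(run["cohort"], seed=run["seed"], epochs=20,
                             arch="vgg5", attention=False, tasks=("classification",))
        vgg_accs.append(res["classification"]["report"].accuracy)
    assert np.mean(resnet_accs) >= np.mean(vgg_accs)
    assert min(resnet_accs) > 25 and min(vgg_accs) > 25
    # fold-to-fold spread stays moderate on strong-signal synthetics
    assert max(resnet_accs) - min(resnet_accs) < 20
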