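"""Split plan, metric blocks, isotonic calibration, model harness."""

import math

import numpy as np
import pytest
from scipy.stats import rankdata

from fhrisk.models import (ResampleAdaBoost, calibrate, classifier_metrics,
                           make_splits, probability_metrics, train_evaluate)


class TestMakeSplits:
    def labels(self, n=100, frac=0.3, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.random(n) < frac).astype(int)

    def test_deterministic_given_seed(self):
        y = self.labels()
        a = make_splits(y, repeats=5, seed=42)
        b = make_splits(y, repeats=5, seed=42)
        assert np.array_equal(a.fold_of, b.fold_of) and a.repeats == b.repeats

    def test_folds_partition_and_repeats_disjoint(self):
        y = self.labels(200)
        plan = make_splits(y, repeats=4, seed=1)
        for rep in range(plan.n_repeats):
            tr, te = plan.indices(rep)
            assert len(np.intersect1d(tr, te)) == 0
            assert len(tr) + len(te) == 200
            train_folds, test_folds = plan.repeats[rep]
            assert sorted(train_folds + test_folds) == list(range(10))
            assert len(train_folds) == 7 and len(test_folds) == 3

    def test_thirty_patients_make_equal_folds(self):
        y = np.tile([0, 0, 1], 10)
        plan = make_splits(y, repeats=1, seed=0)
        sizes = np.bincount(plan.fold_of, minlength=10)
        assert np.all(sizes == 3)

    def test_stratification_balances_positives(self):
        y = self.labels(500, frac=0.2, seed=3)
        plan = make_splits(y, repeats=1, seed=3)
        per_fold = [y[plan.fold_of == k].sum() for k in range(10)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.array([0, 1, 0]), folds=10)


class TestClassifierMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0, 1])
        m = classifier_metrics(y, y.astype(float), y)
        assert m["accuracy"] == 1.0 and m["f_measure"] == 1.0
        assert m["rmse_class"] == 0.0 and m["g_score"] == 1.0

    def test_g_score_from_2x2_counts(self):
        # tool counts tp 140 / fp 387 / fn 4 / tn 5066 as a hard classifier
        hard = np.r_[np.ones(140), np.ones(387), np.zeros(4), np.zeros(5066)]
        truth = np.r_[np.ones(140), np.zeros(387), np.ones(4), np.zeros(5066)]
        m = classifier_metrics(hard, None, truth)
        assert m["g_score"] == pytest.approx(math.sqrt((140 / 144) * (5066 / 5453)))
        assert round(m["g_score"], 4) == 0.9504

    def test_f_measure_hand_value(self):
        hard = np.array([1, 1, 0, 0])
        truth = np.array([1, 0, 1, 0])  # tp 1, fp 1, fn 1
        assert classifier_metrics(hard, None, truth)["f_measure"] == 0.5

    def test_single_class_truth_has_no_rank_auc(self):
        m = classifier_metrics([1, 1], [0.2, 0.8], [1, 1])
        assert m["auc_class"] is None

    def test_rank_auc_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 60)
        score = rng.normal(size=60) + truth
        m = classifier_metrics((score > 0.5).astype(int), score, truth)
        ranks = rankdata(score)
        n1, n0 = truth.sum(), (1 - truth).sum()
        u = ranks[truth == 1].sum() - n1 * (n1 + 1) / 2
        assert m["auc_class"] == pytest.approx(u / (n1 * n0))


class TestProbabilityMetrics:
    def test_perfect_probabilities(self):
        y = np.array([1, 0, 1, 0])
        m = probability_metrics(y.astype(float), y)
        assert m["rmse_prob"] == 0 and m["bs_all"] == 0 and m["cal_mean"] == 0

    def test_constant_half_probability(self):
        y = np.array([1, 0, 1, 0])
        m = probability_metrics(np.full(4, 0.5), y)
        assert m["bs_all"] == 0.25
        assert m["auc_prob"] is None  # constant scores carry no ranking

    def test_hand_arithmetic_example(self):
        m = probability_metrics([0.9, 0.2, 0.6, 0.4], [1, 0, 1, 0])
        assert m["bs_1"] == pytest.approx(0.085)
        assert m["bs_0"] == pytest.approx(0.10)
        assert m["bs_all"] == pytest.approx(0.0925)

    def test_brier_decomposition_identities(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y = (rng.random(n) < 0.3).astype(int)
            p = rng.random(n)
            if y.sum() in (0, n):
                continue
            m = probability_metrics(p, y)
            prev = y.mean()
            assert m["bs_all"] == pytest.approx(
                prev * m["bs_1"] + (1 - prev) * m["bs_0"])
            assert m["rmse_prob"] ** 2 == pytest.approx(m["bs_all"])

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            probability_metrics([1.2, 0.5], [1, 0])

    def test_empty_class_brier_absent(self):
        m = probability_metrics([0.7, 0.8], [1, 1])
        assert m["bs_0"] is None and m["bs_1"] is not None


class TestCalibrate:
    def test_pav_pools_the_violating_pair(self):
        cal = calibrate([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        # the (0.4 -> 0) / (0.35 -> 1) violation pools to 0.5
        assert cal([0.35])[0] == pytest.approx(0.5)
        assert cal([0.4])[0] == pytest.approx(0.5)
        assert cal([0.1])[0] == pytest.approx(0.0)
        assert cal([0.8])[0] == pytest.approx(1.0)

    def test_map_is_monotone_and_clamped(self, rng):
        s = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-s))).astype(int)
        cal = calibrate(s, y)
        grid = np.linspace(-5, 5, 200)
        out = cal(grid)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 0 and out.max() <= 1

    def test_monotone_map_preserves_ranking(self, rng):
        s = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-s))).astype(int)
        cal = calibrate(s, y)
        p = cal(s)
        order = np.argsort(s)
        assert np.all(np.diff(p[order]) >= 0)  # calibrated is monotone in score

    def test_constant_scores_warn_and_map_to_prevalence(self):
        with pytest.warns(UserWarning, match="constant"):
            cal = calibrate([0.5, 0.5, 0.5, 0.5], [0, 1, 1, 1])
        assert cal([0.5])[0] == pytest.approx(0.75)


def separable_data(n=300, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.3, n), rng.normal(size=n)])
    return X, y


class TestTrainEvaluate:
    def test_separable_data_reaches_high_auc(self):
        X, y = separable_data()
        plan = make_splits(y, repeats=2, seed=0)
        rep = train_evaluate("LOG", X, y, plan)
        assert rep.aggregate()["auc_class"]["mean"] >= 0.99

    def test_permuted_labels_are_chance_level(self):
        rng = np.random.default_rng(1)
        X, y = separable_data(n=400, seed=1)
        y_perm = rng.permutation(y)
        plan = make_splits(y_perm, repeats=10, seed=1)
        rep = train_evaluate("LOG", X, y_perm, plan)
        assert abs(rep.aggregate()["auc_class"]["mean"] - 0.5) <= 0.05

    def test_seeded_end_to_end_determinism(self):
        X, y = separable_data(n=200, seed=2)
        plan = make_splits(y, repeats=2, seed=2)
        a = train_evaluate("RF", X, y, plan).to_dict()
        b = train_evaluate("RF", X, y, plan).to_dict()
        assert a == b

    def test_resampling_adaboost_works_without_sample_weights(self):
        # MLP has no sample_weight support; the resampling wrapper must cope
        from sklearn.neural_network import MLPClassifier
        X, y = separable_data(n=250, seed=3)
        model = ResampleAdaBoost(
            build_base=lambda s: MLPClassifier(hidden_layer_sizes=(5,),
                                               max_iter=300, random_state=s),
            n_rounds=5, seed=0).fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.95
        assert len(model.alphas_) == len(model.estimators_) >= 1
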