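import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mccims.classify import (
    DEFAULT_COSTS,
    DEFAULT_TOLERANCES,
    MetricSet,
    ModelSpec,
    balanced_folds,
    compute_metrics,
    permute_labels,
    rank_auc,
    repeated_cv,
    summarize,
    tuning_grid,
)
from mccims.model import FeatureMatrix


def cohort_labels(n_k=30, n_d=39):
    return ["K"] * n_k + ["D"] * n_d


def make_fm(rng, n_k=30, n_d=39, n_signal=3, n_noise=5, effect=2.0):
    """Feature matrix with n_signal differential columns."""
    n = n_k + n_d
    ids = [f"K{i}" for i in range(n_k)] + [f"D{i}" for i in range(n_d)]
    labels = {m: m[0] for m in ids}
    base = rng.lognormal(3.0, 0.3, size=(n, n_signal + n_noise))
    base[n_k:, :n_signal] *= effect
    return FeatureMatrix(
        measurement_ids=ids,
        cluster_ids=[f"c{j}" for j in range(n_signal + n_noise)],
        values=base,
        labels=labels,
    )


class TestBalancedFolds:
    def test_cohort_fold_balance(self):
        labels = cohort_labels()
        folds = balanced_folds(labels, k=10, seed=3)
        for f in range(10):
            members = [labels[i] for i in range(len(labels)) if folds[i] == f]
            assert members.count("K") == 3
            assert members.count("D") in (3, 4)

    def test_single_fold_is_all_data(self):
        folds = balanced_folds(cohort_labels(), k=1, seed=0)
        assert set(folds) == {0}

    def test_deterministic_given_seed(self):
        labels = cohort_labels()
        a = balanced_folds(labels, 10, seed=5)
        b = balanced_folds(labels, 10, seed=5)
        np.testing.assert_array_equal(a, b)
        c = balanced_folds(labels, 10, seed=6)
        assert not np.array_equal(a, c)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            balanced_folds(["K"] * 5 + ["D"] * 40, k=10, seed=0)

    def test_each_sample_in_exactly_one_fold(self):
        folds = balanced_folds(cohort_labels(), k=10, seed=1)
        assert len(folds) == 69 and folds.min() == 0 and folds.max() == 9


class TestMetrics:
    def test_confusion_arithmetic(self):
        truth = ["D"] * 3 + ["K"] + ["K"] * 2 + ["D"]
        scores = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1, 0.3]
        # TP=3 FP=1 TN=2 FN=1
        m = compute_metrics(truth, scores)
        assert m.sensitivity == 0.75
        assert abs(m.specificity - 2 / 3) < 1e-12
        assert m.ppv == 0.75
        assert abs(m.npv - 2 / 3) < 1e-12
        assert abs(m.acc - 5 / 7) < 1e-12

    def test_perfect_separation_auc_one(self):
        m = compute_metrics(["K", "K", "D", "D"], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(11)
        truth = ["D" if v else "K" for v in rng.random(1000) < 0.5]
        m = compute_metrics(truth, rng.random(1000))
        assert 0.45 < m.auc < 0.55

    def test_single_class_auc_undefined(self):
        m = compute_metrics(["D", "D"], [0.6, 0.7])
        assert m.auc is None and m.specificity is None

    def test_auc_matches_sklearn(self):
        rng = np.random.default_rng(4)
        truth = ["D" if v else "K" for v in rng.random(80) < 0.6]
        scores = rng.random(80)
        expected = roc_auc_score([t == "D" for t in truth], scores)
        assert abs(compute_metrics(truth, scores).auc - expected) < 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = rng.random(50) < 0.4
        s = rng.random(50)
        assert rank_auc(y, s) == rank_auc(y, np.exp(5 * s) + 3)

    def test_majority_predictor_properties(self):
        truth = cohort_labels()
        scores = np.ones(len(truth))  # predicts D for everyone
        m = compute_metrics(truth, scores)
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert abs(m.acc - 39 / 69) < 1e-12


class TestRepeatedCV:
    def test_returns_one_metricset_per_repeat(self, rng):
        fm = make_fm(rng, n_k=12, n_d=12)
        results = repeated_cv(fm, ModelSpec(), repeats=2, k=10, seed=0)
        assert len(results) == 2 and all(isinstance(m, MetricSet) for m in results)

    def test_separable_cohort_high_auc_both_families(self, rng):
        fm = make_fm(rng, effect=2.5)
        for family in ("linear_svm", "random_forest"):
            spec = ModelSpec(family=family, n_trees=100)
            results = repeated_cv(fm, spec, repeats=3, k=10, seed=1)
            assert summarize(results)["auc"]["mean"] >= 0.9

    def test_permuted_labels_auc_near_half(self, rng):
        fm = make_fm(rng, effect=2.5)
        fm = FeatureMatrix(
            measurement_ids=fm.measurement_ids,
            cluster_ids=fm.cluster_ids,
            values=fm.values,
            labels=permute_labels(fm.labels, seed=12),
        )
        results = repeated_cv(fm, ModelSpec(), repeats=3, k=10, seed=1)
        assert 0.35 <= summarize(results)["auc"]["mean"] <= 0.65

    def test_reproducible_given_seed(self, rng):
        fm = make_fm(rng, n_k=12, n_d=12)
        a = repeated_cv(fm, ModelSpec(), repeats=2, k=10, seed=7)
        b = repeated_cv(fm, ModelSpec(), repeats=2, k=10, seed=7)
        assert [m.as_dict() for m in a] == [m.as_dict() for m in b]


class TestTuningGrid:
    def test_full_grid_returns_twelve_results(self, rng):
        fm = make_fm(rng, n_k=12, n_d=12)
        grid = tuning_grid(fm, seed=0)
        assert len(grid) == len(DEFAULT_COSTS) * len(DEFAULT_TOLERANCES) == 12

    def test_degenerate_grid_equals_first_cv_repeat(self, rng):
        fm = make_fm(rng, n_k=12, n_d=12)
        grid = tuning_grid(fm, costs=[100.0], tolerances=[0.01], seed=5)
        repeat = repeated_cv(fm, ModelSpec(), repeats=1, k=10, seed=5)[0]
        assert grid[(100.0, 0.01)].as_dict() == repeat.as_dict()

    def test_permuted_grid_worse_than_true_grid(self, rng):
        fm = make_fm(rng, effect=3.0)
        true_grid = tuning_grid(fm, costs=[1.0, 100.0], tolerances=[0.01], seed=2)
        perm_grid = tuning_grid(
            fm, costs=[1.0, 100.0], tolerances=[0.01], seed=2, permute=True
        )
        best_true = max(m.auc for m in true_grid.values())
        best_perm = max(m.auc for m in perm_grid.values())
        assert best_perm < best_true - 0.2


class TestPermuteLabels:
    def test_counts_preserved(self, rng):
        labels = {f"m{i}": ("K" if i % 3 else "D") for i in range(20)}
        out = permute_labels(labels, seed=4)
        assert sorted(out.values()) == sorted(labels.values())
        assert set(out) == set(labels)

    def test_deterministic(self):
        labels = {f"m{i}": ("K" if i < 5 else "D") for i in range(10)}
        assert permute_labels(labels, seed=3) == permute_labels(labels, seed=3)

    def test_both_orders_reachable(self):
        labels = {"a": "K", "b": "D"}
        seen = {tuple(permute_labels(labels, seed=s).values()) for s in range(20)}
        assert seen == {("K", "D"), ("D", "K")}
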