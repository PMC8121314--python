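import numpy as np
import pytest
from scipy import stats

import choroviz as cv
from choroviz.evaluation import (
    classification_metrics,
    evaluate_fold,
    roc_auc,
    stratified_kfold,
    wilcoxon_signed_rank,
)

from oracles import auc_pair_counting, wilcoxon_enumeration


def _labels(n_sym, n_asym):
    return np.array(["symmetric"] * n_sym + ["asymmetric"] * n_asym)


class TestStratifiedKFold:
    def test_cohort_sized_folds(self):
        y = _labels(204, 209)  # near-balanced two-class cohort of 413 eyes
        folds = stratified_kfold(y, k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {41, 42}
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(413))

    def test_leave_one_out_limit(self):
        y = _labels(5, 5)
        folds = stratified_kfold(y, k=10, seed=0)
        assert all(len(f) == 1 for f in folds)

    def test_deterministic_per_seed(self):
        y = _labels(30, 30)
        a = stratified_kfold(y, k=5, seed=3)
        b = stratified_kfold(y, k=5, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_class_balance_within_one(self):
        y = _labels(37, 43)
        for fold in stratified_kfold(y, k=8, seed=1):
            n_sym = (y[fold] == "symmetric").sum()
            assert abs(n_sym - 37 / 8) <= 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(_labels(3, 3), k=10)


class TestRocAuc:
    def test_perfect_separation(self):
        y = _labels(3, 3)
        scores = np.array([0.1, 0.2, 0.15, 0.9, 0.8, 0.95])
        assert roc_auc(scores, y) == 1.0

    def test_reversed_scores_zero(self):
        y = _labels(3, 3)
        scores = np.array([0.9, 0.8, 0.95, 0.1, 0.2, 0.15])
        assert roc_auc(scores, y) == 0.0

    def test_worked_example(self):
        y = np.array(["symmetric", "symmetric", "asymmetric", "asymmetric"])
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), y) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array(["symmetric", "symmetric"]))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = np.where(y == 1, "asymmetric", "symmetric")
            assert roc_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, y)
            )


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = _labels(4, 4)
        m = classification_metrics(y, y)
        assert m == {"accuracy": 1.0, "recall": 1.0, "precision": 1.0, "kappa": 1.0}

    def test_constant_prediction_zero_kappa(self):
        y = _labels(5, 5)
        pred = np.array(["symmetric"] * 10)
        m = classification_metrics(pred, y)
        assert m["kappa"] == pytest.approx(0.0)
        assert m["recall"] == 0.0

    def test_hand_computed_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=5 (positive = asymmetric)
        labels = _labels(6, 4)
        pred = labels.copy()
        pred[0] = "asymmetric"  # one FP
        pred[6] = "symmetric"  # one FN
        m = classification_metrics(pred, labels)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["kappa"] == pytest.approx(7 / 12, abs=1e-9)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        y = np.where(rng.random(50) < 0.5, "symmetric", "asymmetric")
        pred = np.where(rng.random(50) < 0.5, "symmetric", "asymmetric")
        m = classification_metrics(pred, y)
        assert m["kappa"] == pytest.approx(cohen_kappa_score(y, pred))


class TestWilcoxon:
    def test_three_positive_differences(self):
        w, p = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_identical_vectors(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.3, 1, 10)
            _, p = wilcoxon_signed_rank(a, b)
            assert p == pytest.approx(wilcoxon_enumeration(a, b))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        _, p = wilcoxon_signed_rank(a, b)
        p_ref = stats.wilcoxon(a, b, mode="exact").pvalue
        assert p == pytest.approx(p_ref)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 40)
        b = a + rng.normal(0.4, 0.5, 40)
        _, p = wilcoxon_signed_rank(a, b)
        p_ref = stats.wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert p == pytest.approx(p_ref, rel=0.05)


class _ConstantSpec:
    """Deterministic spec scoring by a fixed noisy projection (no training)."""

    def __init__(self, name, flip=False, seed=0):
        self.name = name
        self.flip = flip
        self.seed = seed

    def fit_fold(self, X, images, y, train_idx, seed):
        return self

    def score_cs(self, X, images, idx):
        rng = np.random.default_rng(self.seed)
        base = rng.random(len(X))
        return base[idx] if not self.flip else 1 - base[idx]


class TestModelComparison:
    def test_identical_specs_give_p_one(self, small_benchmark):
        _, _, X, y, _ = small_benchmark
        specs = [_ConstantSpec("a"), _ConstantSpec("b")]
        s = cv.run_model_comparison(X, y, specs, k=5, seed=0)
        assert s.pairwise_p[("a", "b")]["auc"] == 1.0

    def test_folds_shared_between_models(self, small_benchmark):
        _, _, X, y, _ = small_benchmark
        specs = [_ConstantSpec("a"), _ConstantSpec("b", flip=True)]
        s = cv.run_model_comparison(X, y, specs, k=5, seed=0)
        for fa, fb in zip(s.folds["a"], s.folds["b"]):
            assert fa.test_indices == fb.test_indices

    def test_mean_equals_fold_mean(self, small_benchmark):
        _, _, X, y, _ = small_benchmark
        s = cv.run_model_comparison(X, y, [_ConstantSpec("a")], k=5, seed=0)
        mean, _ = s.mean_sd("a", "auc")
        assert mean == pytest.approx(np.mean([f.auc for f in s.folds["a"]]))

    def test_strong_model_beats_shuffled_on_separable_data(self):
        rng = np.random.default_rng(0)
        n = 200
        X = np.vstack(
            [rng.normal(0, 1, (n // 2, 28)), rng.normal(2.5, 1, (n // 2, 28))]
        )
        y = np.array(["symmetric"] * (n // 2) + ["asymmetric"] * (n // 2))
        strong = cv.SVMModelSpec(name="strong", use_gafs=False, hyper={"C": 1.0})
        null = cv.ShuffledLabelSpec(
            base=cv.SVMModelSpec(name="n", use_gafs=False, hyper={"C": 1.0}),
            name="shuffled",
        )
        s = cv.run_model_comparison(X, y, [strong, null], k=10, seed=1)
        assert s.mean_sd("strong", "auc")[0] > 0.95
        assert s.pairwise_p[("strong", "shuffled")]["auc"] < 0.05

    def test_cv_accuracy_tracks_label_noise(self):
        # 10% label noise on separable data: CV accuracy ~ 0.9
        rng = np.random.default_rng(3)
        n = 500
        X = np.vstack(
            [rng.normal(0, 0.5, (n // 2, 10)), rng.normal(3, 0.5, (n // 2, 10))]
        )
        y = np.array(["symmetric"] * (n // 2) + ["asymmetric"] * (n // 2))
        flip = rng.random(n) < 0.1
        y_noisy = y.copy()
        y_noisy[flip] = np.where(y[flip] == "symmetric", "asymmetric", "symmetric")
        pad = np.zeros((n, 18))
        spec = cv.SVMModelSpec(name="svm", use_gafs=False, hyper={"C": 1.0})
        s = cv.run_model_comparison(np.hstack([X, pad]), y_noisy, [spec], k=5, seed=0)
        acc, _ = s.mean_sd("svm", "accuracy")
        assert acc == pytest.approx(0.9, abs=0.05)


class TestEvaluateFold:
    def test_metrics_from_confidence_scores(self):
        labels = np.array(["symmetric", "symmetric", "asymmetric", "asymmetric"])
        cs = np.array([0.9, 0.8, 0.1, 0.6])  # one asymmetric miss
        fr = evaluate_fold(cs, labels, 0, np.arange(4))
        assert fr.accuracy == pytest.approx(0.75)
        assert fr.recall == pytest.approx(0.5)
        assert fr.precision == pytest.approx(1.0)
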