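"""Standardisation, classifier training, metrics and k-fold evaluation."""

import numpy as np
import pytest

from eitbladder.classify import (ClassifierSpec, MetricsReport, apply_standardizer,
                                 evaluate, fit_standardizer,
                                 misclassification_by_factor, run_10fold,
                                 train_classifier, two_threshold_report)
from eitbladder.datasets import make_folds


class TestStandardizer:
    def test_training_transform_is_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.5, (50, 8))
        std = fit_standardizer(X)
        Z = apply_standardizer(std, X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-10)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_hand_computed_column(self):
        std = fit_standardizer(np.array([[1.0], [2.0], [3.0]]))
        Z = std.transform(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(Z.ravel(), [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_constant_column_flagged_and_zeroed(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        std = fit_standardizer(X)
        assert std.constant_mask.tolist() == [False, True]
        assert std.scale[1] == 1.0
        assert np.all(std.transform(X)[:, 1] == 0.0)

    def test_inverse_transform_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        std = fit_standardizer(X)
        assert np.allclose(std.inverse_transform(std.transform(X)), X, atol=1e-10)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.ones((1, 4)))


def _toy_set(n=40, d=12, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-gap / 2, 1.0, (n // 2, d))
    X1 = rng.normal(gap / 2, 1.0, (n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2), dtype=np.int8)
    return X, y


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["linear_svm", "cubic_svm", "cosine_knn"])
    def test_separable_toy_problem(self, kind):
        X, y = _toy_set()
        model = train_classifier(ClassifierSpec(kind, k_neighbours=3), X, y)
        assert np.array_equal(model.predict(X), y)

    def test_two_point_toy_set(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1], dtype=np.int8)
        model = train_classifier(ClassifierSpec("linear_svm"), X, y)
        assert np.array_equal(model.predict(X), y)

    def test_knn_unanimous_vote(self):
        X = np.vstack([np.tile([1.0, 2.0, 3.0], (10, 1)),
                       np.tile([-1.0, -2.0, -3.0], (10, 1))])
        X += np.random.default_rng(0).normal(0, 1e-6, X.shape)
        y = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        model = train_classifier(ClassifierSpec("cosine_knn"), X, y)
        assert model.predict(np.array([[1.0, 2.0, 3.0]]))[0] == 1

    def test_cosine_scale_invariance(self):
        X, y = _toy_set(seed=3)
        model = train_classifier(ClassifierSpec("cosine_knn"), X, y)
        rng = np.random.default_rng(4)
        q = rng.normal(size=(25, X.shape[1]))
        # cosine distance ignores positive rescaling of the *standardised* query
        zq = model.standardizer.transform(q)
        p1 = model.estimator.predict(zq)
        p2 = model.estimator.predict(3.7 * zq)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec("linear_svm"), X, np.zeros(10, np.int8))

    def test_training_order_permutation_invariance(self):
        X, y = _toy_set(n=60, gap=2.0, seed=5)
        perm = np.random.default_rng(6).permutation(len(X))
        m1 = train_classifier(ClassifierSpec("linear_svm"), X, y)
        m2 = train_classifier(ClassifierSpec("linear_svm"), X[perm], y[perm])
        q = np.random.default_rng(7).normal(size=(40, X.shape[1]))
        assert np.array_equal(m1.predict(q), m2.predict(q))

    @pytest.mark.parametrize("kwargs", [
        {"kind": "nope"},
        {"kind": "cosine_knn", "k_neighbours": 0},
        {"kind": "cubic_svm", "kernel_degree": 2},
        {"kind": "linear_svm", "regularization": 0.0},
    ])
    def test_spec_validation(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierSpec(**kwargs)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = MetricsReport.from_predictions([1, 1, 0, 0], [1, 1, 0, 0])
        assert rep.mean_sensitivity == rep.mean_specificity == rep.mean_accuracy == 1.0

    def test_confusion_example(self):
        y = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        rep = MetricsReport.from_predictions(y, pred)
        assert rep.mean_sensitivity == pytest.approx(0.90)
        assert rep.mean_specificity == pytest.approx(0.80)
        assert rep.mean_accuracy == pytest.approx(0.85)
        assert rep.confusion == {"tp": 9, "fn": 1, "tn": 8, "fp": 2}

    def test_all_full_predictor_on_balanced_set(self):
        rep = MetricsReport.from_predictions([1, 1, 0, 0], [1, 1, 1, 1])
        assert rep.mean_sensitivity == 1.0
        assert rep.mean_specificity == 0.0
        assert rep.mean_accuracy == 0.5

    def test_missing_class_reported_as_nan(self):
        rep = MetricsReport.from_predictions([1, 1], [1, 0])
        assert np.isnan(rep.mean_specificity)
        assert np.isnan(rep.mean_accuracy)

    def test_accuracy_identity_holds_per_fold(self):
        rng = np.random.default_rng(2)
        parts = [MetricsReport.from_predictions(rng.integers(0, 2, 30),
                                                rng.integers(0, 2, 30))
                 for _ in range(5)]
        combined = MetricsReport.combine(parts)
        assert np.allclose(combined.accuracy,
                           (combined.sensitivity + combined.specificity) / 2.0)


class TestRunKFold:
    @pytest.fixture(scope="class")
    def fold_run(self, tc1_tiny):
        folds = make_folds(tc1_tiny, 10, seed=0)
        specs = [ClassifierSpec("linear_svm"), ClassifierSpec("cosine_knn")]
        return run_10fold(tc1_tiny, folds, specs, keep_models=True)

    def test_aggregate_equals_mean_of_folds(self, fold_run):
        res = fold_run["linear_svm"]
        assert res.metrics.mean_accuracy == pytest.approx(
            float(np.mean(res.metrics.accuracy)))
        assert len(res.metrics.accuracy) == 10

    def test_models_retained(self, fold_run):
        assert len(fold_run["linear_svm"].models) == 10

    def test_identical_folds_have_zero_sd(self, tc1_tiny):
        # high-SNR tiny TC1 is perfectly separable: all folds at 1.0, sd 0
        folds = make_folds(tc1_tiny, 10, seed=0)
        res = run_10fold(tc1_tiny, folds, [ClassifierSpec("linear_svm")])
        rep = res["linear_svm"].metrics
        assert np.std(rep.accuracy) == pytest.approx(0.0, abs=1e-12)

    def test_misclassification_histograms(self, fold_run, tc1_tiny):
        res = fold_run["linear_svm"]
        hist = misclassification_by_factor(res, tc1_tiny, "volume")
        assert hist.sum() == pytest.approx(
            100.0 * len(res.misclassified) / tc1_tiny.n_obs)
        if len(res.misclassified) == 0:
            assert np.all(hist.values == 0.0)
        with pytest.raises(ValueError):
            misclassification_by_factor(res, tc1_tiny, "colour")

    def test_two_threshold_report(self, fold_run, tc1_tiny):
        rep = two_threshold_report(fold_run["linear_svm"], tc1_tiny)
        assert 0.0 <= rep["below_low_correct"] <= 1.0
        assert 0.0 <= rep["above_high_correct"] <= 1.0


def test_evaluate_on_held_out_data(tc1_tiny):
    rng = np.random.default_rng(0)
    idx = rng.permutation(tc1_tiny.n_obs)
    train, test = idx[:50], idx[50:80]
    model = train_classifier(ClassifierSpec("linear_svm"),
                             tc1_tiny.frames[train], tc1_tiny.labels[train])
    rep = evaluate(model, tc1_tiny.frames[test], tc1_tiny.labels[test])
    assert 0.0 <= rep.mean_accuracy <= 1.0
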