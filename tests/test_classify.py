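"""SVM training protocol, kernel scales, metrics, experiment grid."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fgrs.classify import (
    ExperimentSpec,
    SVMConfig,
    balance_and_split,
    balance_classes,
    cross_validate,
    evaluate_predictions,
    kernel_scale,
    predict_scores,
    run_experiment,
    train_svm,
)
from fgrs.spectra import SpectraSet, Spectrum


def _labelled_set(rng, n_high, n_low, n_channels=12, shift=0.0):
    axis = np.linspace(400, 1800, n_channels)
    spectra = []
    for i in range(n_high):
        y = rng.normal(0, 1, n_channels) + shift
        spectra.append(Spectrum(axis, y, sample_id=f"h{i}", label="high"))
    for i in range(n_low):
        y = rng.normal(0, 1, n_channels)
        spectra.append(Spectrum(axis, y, sample_id=f"l{i}", label="low"))
    return SpectraSet.from_spectra(spectra, label_set=("high", "low"))


def _blobs(rng, n=40, sep=4.0):
    X = np.vstack(
        [rng.normal(0, 1, (n, 2)), rng.normal(sep, 1, (n, 2))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


class TestKernelScale:
    def test_full_spectrum_predictor_count(self):
        assert kernel_scale(571, "medium") == pytest.approx(23.8956, abs=1e-4)
        assert kernel_scale(571, "coarse") == pytest.approx(95.5824, abs=1e-4)

    def test_selected_predictor_count(self):
        assert kernel_scale(82, "medium") == pytest.approx(math.sqrt(82))
        assert kernel_scale(82, "coarse") == pytest.approx(4 * math.sqrt(82))

    def test_single_predictor(self):
        assert kernel_scale(1, "medium") == 1.0
        assert kernel_scale(1, "coarse") == 4.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kernel_scale(0, "medium")
        with pytest.raises(ValueError):
            kernel_scale(10, "fine")


class TestBalanceAndSplit:
    def test_imbalanced_classes_subsampled(self, rng):
        sset = _labelled_set(rng, n_high=459, n_low=95)
        balanced = balance_classes(sset, ("high", "low"), seed=0)
        assert sum(lab == "high" for lab in balanced.labels) == 95
        assert sum(lab == "low" for lab in balanced.labels) == 95

    def test_eighty_twenty_split(self, rng):
        sset = _labelled_set(rng, 100, 100)
        train, hold = balance_and_split(sset, ("high", "low"), 0.8, seed=3)
        for part, n in ((train, 80), (hold, 20)):
            assert sum(lab == "high" for lab in part.labels) == n
            assert sum(lab == "low" for lab in part.labels) == n

    def test_same_seed_same_partition(self, rng):
        sset = _labelled_set(rng, 60, 40)
        a = balance_and_split(sset, ("high", "low"), 0.8, seed=9)
        b = balance_and_split(sset, ("high", "low"), 0.8, seed=9)
        assert a[0].sample_ids == b[0].sample_ids
        assert a[1].sample_ids == b[1].sample_ids

    def test_tiny_class_errors(self, rng):
        sset = _labelled_set(rng, 3, 50)
        with pytest.raises(ValueError):
            balance_classes(sset, ("high", "low"), seed=0)


class TestTrainPredict:
    def test_separable_blobs_perfect_holdout(self, rng):
        X, y = _blobs(rng, n=40)
        train_idx = rng.permutation(80)[:60]
        test_idx = np.setdiff1d(np.arange(80), train_idx)
        model = train_svm(X[train_idx], y[train_idx], SVMConfig("medium"))
        pred, _ = predict_scores(model, X[test_idx])
        assert np.mean(pred == y[test_idx]) == 1.0

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            X, y = _blobs(g, n=20)
            y_perm = g.permutation(y)
            accs.append(
                cross_validate(X, y_perm, SVMConfig("medium", seed=seed), k=5)
            )
        assert abs(np.mean(accs) - 50.0) < 15.0

    def test_single_class_errors(self, rng):
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError):
            train_svm(X, np.zeros(10, dtype=int))

    def test_support_vector_classified_correctly(self, rng):
        X, y = _blobs(rng, n=25)
        model = train_svm(X, y, SVMConfig("medium"))
        sv = model.svc.support_vectors_[0]
        if model.scaler is not None:
            sv = model.scaler.inverse_transform(sv[None, :])
        pred, _ = predict_scores(model, np.atleast_2d(sv))
        sv_index = model.svc.support_[0]
        assert pred[0] == y[sv_index]

    def test_empty_features_error(self, rng):
        X, y = _blobs(rng, n=10)
        model = train_svm(X, y)
        with pytest.raises(ValueError):
            predict_scores(model, np.empty((0, 2)))

    def test_kernel_scale_recorded(self, rng):
        X, y = _blobs(rng, n=10)
        model = train_svm(X, y, SVMConfig("coarse"))
        assert model.kernel_scale == pytest.approx(4 * math.sqrt(2))
        assert model.svc.gamma == pytest.approx(1 / (16 * 2))


class TestCrossValidate:
    def test_separable_blobs_full_accuracy(self, rng):
        X, y = _blobs(rng, n=25, sep=6.0)
        assert cross_validate(X, y, SVMConfig("medium"), k=5) == 100.0

    def test_constant_features_fall_to_chance(self):
        X = np.ones((40, 3))
        y = np.array([0, 1] * 20)
        acc = cross_validate(X, y, SVMConfig("medium"), k=5)
        assert acc == pytest.approx(50.0, abs=10.0)

    def test_class_smaller_than_k_errors(self, rng):
        X, y = _blobs(rng, n=4)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=5)


class TestEvaluate:
    def test_hand_checked_confusion_metrics(self):
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        scores = np.where(y_pred == 1, 1.0, -1.0)
        rep = evaluate_predictions(y_true, y_pred, scores)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 1, 8, 2)
        assert rep.sensitivity == pytest.approx(90.0)
        assert rep.specificity == pytest.approx(80.0)
        assert rep.accuracy == pytest.approx(85.0)

    def test_perfectly_ordered_scores_auc_one(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        scores = np.arange(40, dtype=float)
        rep = evaluate_predictions(y, (scores > 19.5).astype(int), scores)
        assert rep.auc == pytest.approx(1.0)

    def test_random_scores_auc_near_half(self):
        g = np.random.default_rng(7)
        y = g.integers(0, 2, 1000)
        scores = g.normal(size=1000)
        rep = evaluate_predictions(y, (scores > 0).astype(int), scores)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    @given(st.integers(0, 2**31))
    def test_metric_identities_on_random_data(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(4, 60))
        y_true = g.integers(0, 2, n)
        if len(np.unique(y_true)) < 2:
            y_true[0], y_true[1] = 0, 1
        scores = g.normal(size=n)
        y_pred = (scores > 0).astype(int)
        rep = evaluate_predictions(y_true, y_pred, scores)
        total = rep.tp + rep.fn + rep.tn + rep.fp
        assert total == n
        assert rep.accuracy == pytest.approx(100 * (rep.tp + rep.tn) / total)
        assert rep.sensitivity == pytest.approx(
            100 * rep.tp / (rep.tp + rep.fn)
        )
        assert rep.specificity == pytest.approx(
            100 * rep.tn / (rep.tn + rep.fp)
        )
        fpr, tpr = rep.roc[:, 0], rep.roc[:, 1]
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0)

    @given(st.integers(0, 2**31))
    def test_auc_invariant_under_monotone_transform(self, seed):
        g = np.random.default_rng(seed)
        y = g.integers(0, 2, 50)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        scores = g.normal(size=50)
        pred = (scores > 0).astype(int)
        a = evaluate_predictions(y, pred, scores).auc
        b = evaluate_predictions(y, pred, np.exp(scores)).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            evaluate_predictions([1, 0], [1], [0.5])


class TestExperimentGrid:
    def test_grid_structure_and_feature_counts(self, rng):
        train = _labelled_set(rng, 40, 40, n_channels=30, shift=1.5)
        test1 = _labelled_set(rng, 0, 20, n_channels=30)
        test2 = _labelled_set(rng, 20, 20, n_channels=30, shift=1.5)
        spec = ExperimentSpec(cv_folds=3, seed=5)
        table, manifest = run_experiment(
            train, {"testing1": test1, "testing2": test2}, spec
        )
        assert len(table) == 12  # 2 kernels x 2 modes x 3 scenarios
        assert set(table["scenario"]) == {"training", "testing1", "testing2"}
        selected = table[table["feature_mode"] == "selected"]
        assert (selected["n_features"] == manifest["n_selected"]).all()
        assert table["accuracy"].between(0, 100).all()
        assert table["auc"].between(0, 1).all()

    def test_one_class_test_set_completed_from_holdout(self, rng):
        train = _labelled_set(rng, 50, 50, shift=2.0)
        low_only = _labelled_set(rng, 0, 30)
        spec = ExperimentSpec(
            kernels=("coarse",), feature_modes=("all",), cv_folds=3, seed=1
        )
        table, manifest = run_experiment(train, {"testing1": low_only}, spec)
        # holdout has 10 high spectra -> the scenario balances to 10+10
        assert manifest["scenario_sizes"]["testing1"] == 20
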