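"""BCI evaluation criteria: confusion matrix, kappa, ITR, ROC/AUC, LDA, LOO."""

import numpy as np
import pytest

from biosigkit.evaluation import (
    BenchmarkConfig,
    ConfusionMatrix,
    accuracy,
    confusion_matrix,
    correlation,
    information_transfer_rate,
    kappa,
    lda_fit,
    lda_predict,
    leave_one_out_xval,
    mse,
    roc_auc,
    roc_curve,
    run_benchmark_pipeline,
)
from biosigkit.synth_fixtures import make_bci_recording, make_classed_epochs


class TestConfusionMatrix:
    def test_perfect_prediction_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 0], [0, 1, 2, 0], 3)
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_total_conserved_under_label_permutation(self, rng):
        t = rng.integers(0, 3, 100)
        p = rng.integers(0, 3, 100)
        perm = rng.permutation(100)
        assert confusion_matrix(t, p, 3).total == confusion_matrix(t[perm], p[perm], 3).total

    def test_hand_built_2x2(self):
        true_labels = [0] * 50 + [1] * 50
        pred = [0] * 45 + [1] * 5 + [0] * 10 + [1] * 40
        cm = confusion_matrix(true_labels, pred, 2)
        assert np.array_equal(cm.counts, [[45, 5], [10, 40]])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)


class TestAccuracyKappa:
    def test_diagonal_gives_perfect_scores(self):
        cm = ConfusionMatrix(counts=np.diag([10, 20, 30]))
        assert accuracy(cm) == 1.0
        assert kappa(cm) == 1.0

    def test_uniform_matrix_zero_kappa(self):
        cm = ConfusionMatrix(counts=np.full((3, 3), 7))
        assert kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        cm = ConfusionMatrix(counts=np.array([[45, 5], [10, 40]]))
        assert accuracy(cm) == pytest.approx(0.85)
        assert kappa(cm) == pytest.approx(0.70)

    def test_rank_one_expected_table_zero_kappa(self):
        # rows proportional: observed agreement equals chance agreement
        cm = ConfusionMatrix(counts=np.array([[20, 20], [30, 30]]))
        assert kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        t = rng.integers(0, 4, 300)
        p = rng.integers(0, 4, 300)
        cm = confusion_matrix(t, p, 4)
        assert kappa(cm) == pytest.approx(sk.cohen_kappa_score(t, p), abs=1e-12)

    def test_kappa_one_iff_off_diagonal_zero(self):
        cm = ConfusionMatrix(counts=np.array([[10, 1], [0, 10]]))
        assert kappa(cm) < 1.0
        assert kappa(ConfusionMatrix(counts=np.diag([5, 5]))) == 1.0


class TestItr:
    def test_certainty_two_classes_one_bit(self):
        assert information_transfer_rate(1.0, 2, 1.0).bits_per_trial == pytest.approx(1.0)

    def test_chance_two_classes_zero_bits(self):
        assert information_transfer_rate(0.5, 2, 1.0).bits_per_trial == pytest.approx(0.0)

    def test_four_class_example(self):
        expected = 2 + 0.9 * np.log2(0.9) + 0.1 * np.log2(0.1 / 3)
        res = information_transfer_rate(0.9, 4, 4.0)
        assert res.bits_per_trial == pytest.approx(expected)
        assert res.bits_per_minute == pytest.approx(15 * expected)
        assert not res.below_chance

    def test_below_chance_flagged_not_clamped(self):
        with pytest.warns(UserWarning, match="below chance"):
            res = information_transfer_rate(0.2, 4, 1.0)
        assert res.below_chance
        # the raw formula value is reported, not clamped to zero
        expected = 2 + 0.2 * np.log2(0.2) + 0.8 * np.log2(0.8 / 3)
        assert res.bits_per_trial == pytest.approx(expected)

    def test_monotone_in_accuracy_above_chance(self):
        for n in (2, 4):
            values = [
                information_transfer_rate(p, n, 1.0).bits_per_trial
                for p in np.linspace(1.0 / n, 1.0, 20)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
            assert all(v >= -1e-12 for v in values)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_negation_symmetry(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        assert roc_auc(-scores, labels) == pytest.approx(1 - roc_auc(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        assert roc_auc(np.exp(scores), labels) == pytest.approx(roc_auc(scores, labels))

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        scores = rng.normal(size=500).round(1)  # ties included
        labels = rng.integers(0, 2, 500)
        assert roc_auc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_endpoints(self, rng):
        fpr, tpr = roc_curve(rng.normal(size=50), rng.integers(0, 2, 50))
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, dtype=int))


class TestCorrelationMse:
    def test_identity_and_negation(self, rng):
        x = rng.normal(size=50)
        assert correlation(x, x) == pytest.approx(1.0)
        assert correlation(x, -x) == pytest.approx(-1.0)
        assert mse(x, x) == 0.0

    def test_hand_computed_values(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 4, 7])
        assert correlation(x, y) == pytest.approx(0.9934, abs=1e-4)
        assert mse(x, y) == pytest.approx((1 + 4 + 16) / 3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(10), np.arange(10.0))


class TestLda:
    def _gaussian_classes(self, rng, n=100, d=2, delta=4.0):
        X0 = rng.normal(0, 1, size=(n, d))
        X1 = rng.normal(0, 1, size=(n, d)) + delta / np.sqrt(d)
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separable_classes_high_accuracy(self, rng):
        X, y = self._gaussian_classes(rng, delta=4.0)
        clf = lda_fit(X, y)
        pred, _ = lda_predict(clf, X)
        assert (pred == y).mean() >= 0.95

    def test_identical_distributions_chance_accuracy(self, rng):
        X, y = self._gaussian_classes(rng, n=500, delta=0.0)
        clf = lda_fit(X, y)
        pred, _ = lda_predict(clf, X)
        assert abs((pred == y).mean() - 0.5) < 0.1

    def test_one_dimensional_midpoint_boundary(self):
        X = np.array([[0.0], [1.0], [0.2], [10.0], [11.0], [10.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = lda_fit(X, y)
        mid = (X[y == 0].mean() + X[y == 1].mean()) / 2
        below, _ = lda_predict(clf, np.array([[mid - 0.1]]))
        above, _ = lda_predict(clf, np.array([[mid + 0.1]]))
        assert below[0] == 0 and above[0] == 1

    def test_matches_sklearn_predictions(self, rng):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = self._gaussian_classes(rng, n=80, d=3, delta=1.5)
        clf = lda_fit(X, y)
        pred, _ = lda_predict(clf, X)
        ref = sk.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y).predict(X)
        assert (pred == ref).mean() > 0.99

    def test_singular_covariance_suggests_shrinkage(self, rng):
        X = np.repeat(rng.normal(size=(8, 1)), 3, axis=1)  # rank-1 features
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="shrinkage"):
            lda_fit(X, y)
        clf = lda_fit(X, y, shrinkage=0.5)  # regularized fit succeeds
        assert np.isfinite(clf.weights).all()

    def test_class_with_one_trial_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(np.zeros((3, 1)), [0, 0, 1])


class TestLeaveOneOut:
    def test_constant_predictor_majority_accuracy(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 14 + [1] * 6)

        def fit(Xtr, ytr):
            return int(np.bincount(ytr).argmax())

        def predict(model, Xte):
            return np.full(len(Xte), model)

        cm, acc = leave_one_out_xval(X, y, fit=fit, predict=predict)
        assert acc == pytest.approx(14 / 20)

    def test_hand_traced_three_trials(self):
        """n=3 in 1-D, enumerable by hand with a nearest-mean rule."""
        X = np.array([[0.0], [1.0], [10.0]])
        y = np.array([0, 0, 1])

        def fit(Xtr, ytr):
            return {c: Xtr[ytr == c].mean() for c in np.unique(ytr)}

        def predict(means, Xte):
            classes = sorted(means)
            dists = [abs(Xte[0, 0] - means[c]) for c in classes]
            return np.array([classes[int(np.argmin(dists))]])

        # fold 1: train {1, 10}, test 0 -> predicts 0 (|0-1| < |0-10|)
        # fold 2: train {0, 10}, test 1 -> predicts 0
        # fold 3: train {0, 1}: class 1 lost -> fold excluded
        cm, acc = leave_one_out_xval(X, y, fit=fit, predict=predict)
        assert cm.total == 2
        assert np.array_equal(cm.counts, [[2, 0], [0, 0]])
        assert acc == 1.0

    def test_loo_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        y[:4] = [0, 0, 1, 1]
        cm1, a1 = leave_one_out_xval(X, y)
        cm2, a2 = leave_one_out_xval(X, y)
        assert np.array_equal(cm1.counts, cm2.counts) and a1 == a2

    def test_loo_not_more_optimistic_than_training(self):
        """On average over seeds, LOO accuracy <= training accuracy."""
        diffs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(1.5, 1, (15, 2))])
            y = np.array([0] * 15 + [1] * 15)
            clf = lda_fit(X, y)
            pred, _ = lda_predict(clf, X)
            train_acc = (pred == y).mean()
            _, loo_acc = leave_one_out_xval(X, y)
            diffs.append(train_acc - loo_acc)
        assert np.mean(diffs) >= 0


class TestBenchmarkPipeline:
    def test_class_dependent_fixture_high_accuracy(self):
        rec = make_bci_recording()
        report = run_benchmark_pipeline(rec, BenchmarkConfig(class_codes=(769, 770)))
        assert report.accuracy >= 0.9
        assert report.kappa > 0.7
        assert report.n_epochs == 60

    def test_null_fixture_chance_accuracy(self):
        rec = make_bci_recording(amplitudes=(1.0, 1.0), n_per_class=40)
        report = run_benchmark_pipeline(rec, BenchmarkConfig(class_codes=(769, 770)))
        # binomial 95% interval around 0.5 at n=80 is ~ +/- 0.11
        assert abs(report.accuracy - 0.5) < 0.15

    def test_deterministic_given_seed_and_config(self):
        cfg = BenchmarkConfig(class_codes=(769, 770))
        r1 = run_benchmark_pipeline(make_bci_recording(seed=5), cfg)
        r2 = run_benchmark_pipeline(make_bci_recording(seed=5), cfg)
        assert np.array_equal(r1.confusion.counts, r2.confusion.counts)
        assert r1.accuracy == r2.accuracy
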