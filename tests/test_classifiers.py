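import numpy as np
import pytest
from scipy.stats import norm

from actiseq.classifiers import (
    ConfusionMatrix,
    GMMClassifier,
    KNNClassifier,
    NaiveBayesClassifier,
    NearestMeanClassifier,
    ParzenClassifier,
    aggregate_confusions,
    evaluate,
    fit_gaussian_mixture,
    fit_geometric,
    fit_probabilistic,
)
from actiseq.selection import LabelledFeatureSet


def _two_gaussians_1d(rng, n=500, means=(0.0, 4.0)):
    x = np.concatenate([rng.normal(means[0], 1, n), rng.normal(means[1], 1, n)])
    y = np.array(["c0"] * n + ["c1"] * n)
    return x[:, None], y


class TestGaussianMixtureFit:
    def test_single_component_closed_form(self, rng):
        x = rng.standard_normal((50, 3)) + [1, 2, 3]
        w, mu, cov = fit_gaussian_mixture(x, 1)
        np.testing.assert_array_equal(mu[0], x.mean(axis=0))
        assert w[0] == 1.0

    def test_em_recovers_two_separated_modes(self, rng):
        x = np.vstack([rng.normal(-4, 1, (300, 1)), rng.normal(4, 1, (300, 1))])
        w, mu, cov = fit_gaussian_mixture(x, 2, seed=0)
        assert sorted(np.round(mu.ravel())) == [-4, 4]
        np.testing.assert_allclose(w.sum(), 1.0)


class TestProbabilisticClassifiers:
    def test_fitted_means_near_truth(self, rng):
        x, y = _two_gaussians_1d(rng)
        clf = GMMClassifier(n_components=1).fit(x, y)
        fitted = sorted(m[1][0, 0] for m in clf.models_)
        assert abs(fitted[0] - 0.0) < 0.2 and abs(fitted[1] - 4.0) < 0.2

    def test_hand_computed_density_decision(self, rng):
        """x = 1.0 under N(0,1) vs N(4,1): densities 0.2420 vs 0.0044."""
        x, y = _two_gaussians_1d(rng)
        clf = GMMClassifier(n_components=1).fit(x, y)
        assert norm.pdf(1.0, 0, 1) == pytest.approx(0.2420, abs=1e-4)
        assert norm.pdf(1.0, 4, 1) == pytest.approx(0.0044, abs=1e-4)
        assert clf.predict(np.array([[1.0]]))[0] == "c0"

    def test_point_at_class_mean_wins(self, rng):
        x = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(8, 1, (50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        for kind in ("nb", "gmm", "parzen"):
            clf = fit_probabilistic(LabelledFeatureSet(x, y), kind)
            assert clf.predict(np.array([[8.0, 8.0]]))[0] == "b"

    def test_midpoint_tie_breaks_to_lower_class(self):
        # perfectly symmetric classes around 2.0; tie at the midpoint
        x = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array(["a", "a", "b", "b"])
        clf = GMMClassifier(n_components=1).fit(x, y)
        assert clf.predict(np.array([[2.0]]))[0] == "a"

    def test_parzen_density_maximal_at_single_training_point(self):
        clf = ParzenClassifier(bandwidth=1.0)
        clf.fit(np.array([[2.0, 2.0], [9.0, 9.0]]), np.array(["a", "b"]))
        dens = clf.class_log_density(np.array([[2.0, 2.0], [2.5, 2.0]]))
        assert dens[0, 0] > dens[1, 0]

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayesClassifier().fit(np.array([[1.0], [2.0]]), np.array(["a", "b"]))


class TestGeometricClassifiers:
    def test_nearest_mean_example(self):
        clf = NearestMeanClassifier().fit(
            np.array([[0.0], [0.0], [10.0], [10.0]]), np.array(["lo", "lo", "hi", "hi"])
        )
        assert clf.predict(np.array([[1.0]]))[0] == "lo"

    def test_one_nn_returns_nearest_label(self, rng):
        x = rng.standard_normal((20, 2))
        y = np.array([f"c{i % 4}" for i in range(20)])
        clf = KNNClassifier(k=1).fit(x, y)
        preds = clf.predict(x + 1e-9)
        np.testing.assert_array_equal(preds, y)

    def test_majority_vote(self):
        x = np.array([[0.0], [0.1], [0.2], [5.0], [9.0], [9.1]])
        y = np.array(["A", "A", "B", "B", "B", "B"])
        clf = KNNClassifier(k=3).fit(x, y)
        # neighbours of 0.05: {A, A, B} -> A
        assert clf.predict(np.array([[0.05]]))[0] == "A"

    def test_knn_with_k_equal_n_is_majority_class(self, rng):
        x = rng.standard_normal((30, 2))
        y = np.array(["maj"] * 20 + ["min"] * 10)
        clf = KNNClassifier(k=30).fit(x, y)
        assert all(p == "maj" for p in clf.predict(rng.standard_normal((10, 2))))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            NearestMeanClassifier().fit(np.empty((0, 2)), np.array([]))
        with pytest.raises(ValueError):
            fit_geometric(
                LabelledFeatureSet(np.ones((4, 1)), np.array(list("abab"))), "bogus"
            )


class TestMahalanobisEquivalence:
    def test_shared_covariance_gmm_equals_mahalanobis_nearest_mean(self, rng):
        """With one shared Gaussian per class, the max-density rule reduces to
        nearest mean under the Mahalanobis metric of the shared covariance."""
        a = rng.normal(0, 1, (100, 3)) @ np.diag([1.0, 2.0, 0.5])
        b = a + [3, -2, 1]
        x = np.vstack([a, b])
        y = np.array(["a"] * 100 + ["b"] * 100)
        clf = GMMClassifier(n_components=1).fit(x, y)
        shared = np.mean([m[2][0] for m in clf.models_], axis=0)
        for i in range(len(clf.models_)):
            w, mu, _ = clf.models_[i]
            clf.models_[i] = (w, mu, shared[None, :, :])
        means = np.array([m[1][0] for m in clf.models_])
        inv = np.linalg.inv(shared)
        queries = rng.normal(1, 2, (50, 3))
        pred = clf.predict(queries)
        for q, p in zip(queries, pred):
            d2 = [ (q - m) @ inv @ (q - m) for m in means ]
            assert p == clf.classes_[int(np.argmin(d2))]


class TestConfusionMatrices:
    def test_perfect_classifier_identity(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = NearestMeanClassifier().fit(x, y)
        cm = evaluate(clf, LabelledFeatureSet(x, y))
        assert cm.accuracy == 1.0
        assert np.trace(cm.counts) == 40

    def test_hand_counted_accuracy(self):
        cm = ConfusionMatrix.from_predictions(
            ["a", "a", "b", "b"], ["a", "a", "b", "a"], ["a", "b"]
        )
        assert cm.accuracy == 0.75

    def test_row_sums_conserve_class_counts(self, rng):
        y_true = rng.choice(["a", "b", "c"], 60)
        y_pred = rng.choice(["a", "b", "c"], 60)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, ["a", "b", "c"])
        for i, lab in enumerate(cm.labels):
            assert cm.counts[i].sum() == (y_true == lab).sum()

    def test_aggregation_identity_and_conservation(self):
        cm1 = ConfusionMatrix.from_predictions(["a", "b"] * 5, ["a", "b"] * 5, ["a", "b"])
        cm2 = ConfusionMatrix.from_predictions(
            ["a"] * 12 + ["b"] * 8, ["a"] * 10 + ["b"] * 10, ["a", "b"]
        )
        assert aggregate_confusions([cm1]).counts.tolist() == cm1.counts.tolist()
        agg = aggregate_confusions([cm1, cm2])
        assert agg.total == cm1.total + cm2.total

    def test_aggregate_accuracy_is_outcome_weighted_mean(self):
        cm1 = ConfusionMatrix(np.array([[8, 2], [0, 10]]), ["a", "b"])
        cm2 = ConfusionMatrix(np.array([[3, 0], [3, 4]]), ["a", "b"])
        agg = aggregate_confusions([cm1, cm2])
        weighted = (cm1.accuracy * cm1.total + cm2.accuracy * cm2.total) / (
            cm1.total + cm2.total
        )
        assert agg.accuracy == pytest.approx(weighted)

    def test_mismatched_labels_rejected(self):
        cm1 = ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])
        cm2 = ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "c"])
        with pytest.raises(ValueError):
            aggregate_confusions([cm1, cm2])
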