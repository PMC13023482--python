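"""Prototype classifiers, WWKNN, selective metrics, seed sweeps."""

import numpy as np
import pytest

from braincube.classify import (
    DONT_KNOW,
    LearnedPrototypeConfig,
    Normaliser,
    balance_by_duplication,
    fit_centroid,
    fit_learned_prototype,
    fit_wwknn,
    predict,
    predict_proba,
    rbf_kernel,
    seed_sweep,
    selective_metrics,
    selective_predict,
    wwknn_predict,
)


class TestCentroid:
    def test_axis_aligned_classes(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        ps = fit_centroid(X, y)
        np.testing.assert_allclose(ps.prototypes, np.eye(2), atol=1e-12)

    def test_mean_then_normalise(self):
        X = np.array([[2.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        y = np.array([0, 0, 1])
        ps = fit_centroid(X, y)
        np.testing.assert_allclose(ps.prototypes[0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(ps.prototypes[1], [0.0, 1.0], atol=1e-12)

    def test_zero_norm_centroid_rejected(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="zero norm"):
            fit_centroid(X, np.array([0, 0]))


class TestLearnedPrototype:
    def _clusters(self, rng, n=40, sep=4.0):
        # angularly separated clusters (cosine-similarity classifiers
        # discriminate directions, not offsets)
        X0 = rng.normal([sep, 0.0], 0.4, (n, 2))
        X1 = rng.normal([0.0, sep], 0.4, (n, 2))
        return np.vstack([X0, X1]), np.array([0] * n + [1] * n)

    def test_zero_epochs_equals_centroid(self, rng):
        X, y = self._clusters(rng)
        ps0 = fit_learned_prototype(X, y, LearnedPrototypeConfig(epochs=0))
        psc = fit_centroid(X, y)
        np.testing.assert_allclose(ps0.prototypes, psc.prototypes, atol=1e-12)
        Q = rng.normal(2, 3, (50, 2))
        np.testing.assert_array_equal(predict(ps0, Q), predict(psc, Q))

    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        X, y = self._clusters(rng, sep=5.0)
        ps = fit_learned_prototype(X, y)
        assert np.mean(predict(ps, X) == y) == 1.0

    def test_training_reduces_loss(self, rng):
        X, y = self._clusters(rng, sep=1.5)

        def loss(ps):
            p = predict_proba(ps, X)
            idx = np.searchsorted(ps.classes, y)
            return -np.mean(np.log(p[np.arange(len(y)), idx]))

        before = loss(fit_learned_prototype(X, y, LearnedPrototypeConfig(epochs=0)))
        after = loss(fit_learned_prototype(X, y, LearnedPrototypeConfig(epochs=300)))
        assert after < before

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_learned_prototype(np.ones((3, 2)), np.zeros(3))


class TestPredictProba:
    def test_hand_value_for_orthogonal_prototypes(self):
        from braincube.classify import PrototypeSet

        ps = PrototypeSet(np.eye(2), np.array([0, 1]), tau=0.1)
        p = predict_proba(ps, np.array([1.0, 0.0]))
        np.testing.assert_allclose(p[0, 0], 1.0 / (1.0 + np.exp(-10.0)), rtol=1e-12)

    def test_equidistant_state_is_uniform(self):
        from braincube.classify import PrototypeSet

        ps = PrototypeSet(np.eye(2), np.array([0, 1]), tau=0.1)
        p = predict_proba(ps, np.array([1.0, 1.0]))
        np.testing.assert_allclose(p[0], [0.5, 0.5], atol=1e-12)

    def test_scale_invariance(self, rng):
        from braincube.classify import PrototypeSet

        protos = rng.normal(size=(3, 5))
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        ps = PrototypeSet(protos, np.arange(3), tau=0.1)
        x = rng.normal(size=5)
        np.testing.assert_allclose(predict_proba(ps, x), predict_proba(ps, 7.3 * x),
                                   rtol=1e-9)


class TestWWKNN:
    def test_uninformative_feature_annihilated(self, rng):
        # feature 1 identical class means/variance -> SNR ~ 0
        n = 60
        y = np.array([0] * n + [1] * n)
        f0 = np.concatenate([rng.normal(0, 0.3, n), rng.normal(3, 0.3, n)])
        f1 = rng.normal(0, 1.0, 2 * n)
        model = fit_wwknn(np.column_stack([f0, f1]), y, k=5)
        assert model.snr[0] > 50 * model.snr[1]

    def test_matches_plain_knn_on_single_informative_feature(self, rng):
        """Brute-force oracle: when only feature 0 separates the classes,
        WWKNN predictions equal unweighted kNN on feature 0 alone."""
        n = 40
        y = np.array([0] * n + [1] * n)
        f0 = np.concatenate([rng.normal(0, 0.4, n), rng.normal(4, 0.4, n)])
        X = np.column_stack([f0, np.zeros(2 * n)])  # second feature constant
        model = fit_wwknn(X, y, k=5)
        Q = np.column_stack([rng.uniform(-1, 5, 30), np.zeros(30)])
        got, _ = wwknn_predict(model, Q)
        # oracle: plain distance-weighted kNN on feature 0
        expected = []
        for q in Q[:, 0]:
            d = np.abs(f0 - q)
            nn = np.argsort(d, kind="stable")[:5]
            w = 1.0 / (d[nn] + 1e-12)
            votes = [w[y[nn] == c].sum() for c in (0, 1)]
            expected.append(int(np.argmax(votes)))
        np.testing.assert_array_equal(got, expected)

    def test_k_equal_n_predicts_weighted_majority(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0]])
        y = np.array([0, 0, 0, 1])
        model = fit_wwknn(X, y, k=4)
        got, conf = wwknn_predict(model, np.array([[0.05]]))
        assert got[0] == 0 and conf[0] > 0.5

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            fit_wwknn(np.ones((3, 2)), np.array([0, 1, 0]), k=0)
        model = fit_wwknn(np.ones((3, 2)), np.array([0, 1, 0]), k=3)
        model.k = 10
        with pytest.raises(ValueError):
            wwknn_predict(model, np.ones((1, 2)))


class TestRBFKernel:
    def test_identity_and_hand_value(self):
        x = np.array([1.0, 2.0])
        assert rbf_kernel(x, x, gamma=0.3) == 1.0
        # ||xi - xj||^2 = 1/gamma -> e^-1
        y = x + np.array([np.sqrt(2.0), 0.0])
        np.testing.assert_allclose(rbf_kernel(x, y, gamma=0.5), np.exp(-1.0), rtol=1e-12)

    def test_symmetry_and_default_gamma(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert rbf_kernel(a, b) == rbf_kernel(b, a)
        np.testing.assert_allclose(
            rbf_kernel(a, b), np.exp(-np.sum((a - b) ** 2) / 4.0), rtol=1e-12
        )


class TestSelective:
    def test_threshold_extremes(self):
        probs = np.array([[0.58, 0.42], [0.9, 0.1]])
        assert not np.any(selective_predict(probs, 0.0) == DONT_KNOW)
        assert np.all(selective_predict(probs, 1.0) == DONT_KNOW)
        np.testing.assert_array_equal(selective_predict(probs, 0.60),
                                      [DONT_KNOW, 0])

    def _synthetic_run(self, correct, wrong, rejected, lost_correct):
        """Build per-sample arrays realising the requested counts."""
        n = correct + wrong + rejected
        truth = np.zeros(n, dtype=int)
        sel = np.concatenate([
            np.zeros(correct, dtype=int),          # accepted correct
            np.ones(wrong, dtype=int),             # accepted wrong
            np.full(rejected, DONT_KNOW),
        ])
        forced = np.concatenate([
            np.zeros(correct, dtype=int),
            np.ones(wrong, dtype=int),
            np.zeros(lost_correct, dtype=int),     # rejected, forced correct
            np.ones(rejected - lost_correct, dtype=int),
        ])
        return truth, sel, forced

    def test_printed_style_row(self):
        truth, sel, forced = self._synthetic_run(208, 26, 66, 35)
        rep = selective_metrics(truth, sel, forced, threshold=0.60)
        assert (rep.coverage, rep.selective_accuracy, rep.overall_accuracy) == (
            78.0, 88.9, 81.0)
        assert rep.correct + rep.wrong + rep.rejected == rep.n == 300
        assert rep.rejected == rep.lost_correct + rep.errors_avoided == 66
        assert rep.errors_avoided == 31

    def test_zero_rejections_collapses_accuracies(self):
        truth, sel, forced = self._synthetic_run(80, 20, 0, 0)
        rep = selective_metrics(truth, sel, forced)
        assert rep.coverage == 100.0
        assert rep.selective_accuracy == rep.overall_accuracy == 80.0

    def test_all_rejected_sentinel(self):
        truth, sel, forced = self._synthetic_run(0, 0, 10, 4)
        rep = selective_metrics(truth, sel, forced)
        assert rep.coverage == 0.0 and rep.selective_accuracy is None
        assert rep.overall_accuracy == 40.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            selective_metrics([0, 1], [0], [0, 1])

    def test_selective_accuracy_monotone_for_calibrated_confidence(self, rng):
        """With confidence equal to the true correctness probability, raising
        the threshold never lowers selective accuracy."""
        n = 4000
        conf = rng.uniform(0.5, 1.0, n)
        correct = rng.random(n) < conf
        truth = np.zeros(n, dtype=int)
        forced = np.where(correct, 0, 1)
        last = 0.0
        for thr in (0.0, 0.6, 0.7, 0.8, 0.9):
            sel = np.where(conf >= thr, forced, DONT_KNOW)
            rep = selective_metrics(truth, sel, forced, thr)
            assert rep.selective_accuracy >= last - 1e-9
            last = rep.selective_accuracy


class TestSeedSweep:
    def test_hand_computed_summary(self):
        accs = iter([0.8, 0.8, 0.9, 0.9])
        res = seed_sweep(lambda s: next(accs), seeds=[0, 1, 2, 3])
        np.testing.assert_allclose(res["mean"], 0.85, atol=1e-12)
        np.testing.assert_allclose(res["std"], 0.057735026918962574, rtol=1e-9)

    def test_deterministic_fit_degenerate_ci(self):
        res = seed_sweep(lambda s: 0.7, seeds=list(range(5)))
        assert res["std"] == 0.0
        assert res["ci95"] == (0.7, 0.7)

    def test_ci_width_scales_inverse_sqrt(self, rng):
        f = lambda s: float(np.random.default_rng(s).normal(0.8, 0.05))
        r1 = seed_sweep(f, seeds=list(range(30)))
        r2 = seed_sweep(f, seeds=list(range(120)))
        w1 = r1["ci95"][1] - r1["ci95"][0]
        w2 = r2["ci95"][1] - r2["ci95"][0]
        assert w2 < 0.75 * w1  # roughly halves when n quadruples

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError):
            seed_sweep(lambda s: 0.5, seeds=[0])


def test_normaliser_and_balancing(rng):
    X = rng.normal([5, -2], [2, 0.5], (200, 2))
    norm = Normaliser.fit(X)
    Z = norm.transform(X)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)
    y = np.array([0] * 30 + [1] * 10)
    Xb, yb = balance_by_duplication(np.arange(40)[:, None], y, seed=0)
    assert (yb == 0).sum() == (yb == 1).sum() == 30
    assert set(Xb[yb == 1, 0]) <= set(np.arange(30, 40))
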