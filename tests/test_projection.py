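"""Alignment-maximizing projection: distances, objective, gradient, fitting,
relevance."""

import numpy as np
import pytest

from ckainit import (
    DegenerateKernelError,
    OptimizerConfig,
    cka,
    cka_gradient,
    cka_objective,
    fit_cka_projection,
    gaussian_kernel,
    label_kernel,
    relevance,
    sq_mahalanobis,
    top_k_features,
)
from ckainit.projection import group_relevance


def finite_diff_gradient(W, X, t, h=1e-6):
    """Central-difference oracle for the objective gradient."""
    fd = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += h
            Wm[i, j] -= h
            fd[i, j] = (cka_objective(Wp, X, t) - cka_objective(Wm, X, t)) / (2 * h)
    return fd


class TestSqMahalanobis:
    def test_identity_gives_euclidean(self, rng):
        X = rng.standard_normal((6, 3))
        D2 = sq_mahalanobis(X, np.eye(3))
        diff = X[:, None, :] - X[None, :, :]
        np.testing.assert_allclose(D2, np.sum(diff**2, axis=2), atol=1e-10)

    def test_zero_projection_gives_zero(self, rng):
        X = rng.standard_normal((5, 4))
        assert np.all(sq_mahalanobis(X, np.zeros((2, 4))) == 0.0)

    def test_hand_computed_entry(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        W = np.array([[2.0, 0.0], [0.0, 1.0]])
        D2 = sq_mahalanobis(X, W)
        assert D2[0, 1] == pytest.approx(5.0)  # ||(2, -1)||^2

    def test_symmetry_zero_diagonal_nonnegative(self, rng):
        X = rng.standard_normal((8, 5))
        W = rng.standard_normal((3, 5))
        D2 = sq_mahalanobis(X, W)
        np.testing.assert_allclose(D2, D2.T)
        assert np.all(np.diag(D2) == 0.0)
        assert np.all(D2 >= 0.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            sq_mahalanobis(rng.standard_normal((4, 3)), np.eye(2))


class TestObjective:
    def test_affine_construction_reaches_one(self):
        X = np.array([[0.0], [0.0], [1.0]])
        t = np.array([1, 1, 2])
        assert cka_objective(np.array([[1.0]]), X, t) == pytest.approx(1.0, abs=1e-10)

    def test_zero_projection_degenerate(self):
        X = np.arange(6.0).reshape(3, 2)
        with pytest.raises(DegenerateKernelError):
            cka_objective(np.zeros((1, 2)), X, np.array([1, 2, 1]))

    def test_single_class_degenerate(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(DegenerateKernelError, match="single class"):
            cka_objective(np.eye(2), X, np.array([1, 1, 1, 1]))

    def test_equals_chained_brute_force(self, rng):
        X = rng.standard_normal((8, 3))
        t = rng.integers(1, 3, size=8)
        W = rng.standard_normal((2, 3))
        # scalar-loop composition of the kernel chain
        d2 = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                v = W @ (X[i] - X[j])
                d2[i, j] = v @ v
        expected = cka(gaussian_kernel(d2, 1.0), label_kernel(t))
        assert cka_objective(W, X, t) == pytest.approx(expected, abs=1e-12)


class TestGradient:
    def test_matches_finite_differences_many_instances(self):
        """Mandatory oracle: analytic gradient vs central differences on 20
        random small instances, relative error < 1e-5 elementwise."""
        gen = np.random.default_rng(42)
        for _ in range(20):
            X = gen.standard_normal((10, 4))
            t = gen.integers(1, 4, size=10)
            if np.unique(t).size < 2:
                t[0] = 1 + (t[0] % 3)
            W = gen.standard_normal((2, 4)) * gen.uniform(0.3, 1.5)
            g = cka_gradient(W, X, t)
            fd = finite_diff_gradient(W, X, t)
            denom = np.maximum(np.abs(fd), 1e-4 * np.abs(fd).max())
            assert np.max(np.abs(g - fd) / denom) < 1e-5

    def test_stationary_at_alignment_maximum(self):
        # rho = 1 is the global maximum of a smooth bounded objective, so the
        # gradient must vanish there (affine-in-labels construction).
        X = np.array([[0.0], [0.0], [1.0]])
        t = np.array([1, 1, 2])
        g = cka_gradient(np.array([[1.0]]), X, t)
        assert np.linalg.norm(g) < 1e-6

    def test_scaled_input_consistency(self):
        gen = np.random.default_rng(3)
        X = gen.standard_normal((9, 3))
        t = gen.integers(1, 3, size=9)
        for c in (0.5, 2.0):
            W = gen.standard_normal((2, 3)) * c
            fd = finite_diff_gradient(W, X, t)
            g = cka_gradient(W, X, t)
            denom = np.maximum(np.abs(fd), 1e-4 * np.abs(fd).max())
            assert np.max(np.abs(g - fd) / denom) < 1e-5


class TestFit:
    def test_recovers_informative_feature(self, two_class_blobs):
        X, t = two_class_blobs
        Xs = (X - X.mean(0)) / X.std(0)
        model = fit_cka_projection(Xs, t, 2, OptimizerConfig(seed=0))
        assert model.rho > model.trace[0][1]
        assert top_k_features(model.relevance, 1)[0] == 0

    def test_trace_strictly_increasing(self, two_class_blobs):
        X, t = two_class_blobs
        for seed in (0, 1, 2):
            model = fit_cka_projection(X, t, 2, OptimizerConfig(seed=seed, init="random"))
            rhos = [r for _, r in model.trace]
            assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_infinite_tol_returns_initialization(self, two_class_blobs):
        X, t = two_class_blobs
        model = fit_cka_projection(X, t, 2, OptimizerConfig(tol=np.inf, seed=0))
        assert len(model.trace) == 1  # no accepted steps

    def test_same_seed_bitwise_identical(self, two_class_blobs):
        X, t = two_class_blobs
        cfg = OptimizerConfig(seed=5, init="random", max_iter=20)
        m1 = fit_cka_projection(X, t, 2, cfg)
        m2 = fit_cka_projection(X, t, 2, cfg)
        assert np.array_equal(m1.W, m2.W)

    def test_scale_handling(self, two_class_blobs):
        # doubling X: the median-distance normalization makes the fit depend
        # only on the shape of the point cloud, so final rho agrees
        X, t = two_class_blobs
        cfg = OptimizerConfig(seed=0, max_iter=30)
        r1 = fit_cka_projection(X, t, 2, cfg).rho
        r2 = fit_cka_projection(2.0 * X, t, 2, cfg).rho
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_m1_constraints(self, two_class_blobs):
        X, t = two_class_blobs
        with pytest.raises(ValueError, match="m1"):
            fit_cka_projection(X, t, 6)  # m1 > D = 5
        with pytest.raises(ValueError, match="samples"):
            fit_cka_projection(X[:2], t[:2], 2)  # N <= m1


class TestRelevance:
    def test_identity_is_uniform(self):
        np.testing.assert_allclose(relevance(np.eye(4)), np.ones(4))

    def test_hand_arithmetic(self):
        W = np.array([[2.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(relevance(W, normalize=False), [2.0, 0.5])
        np.testing.assert_allclose(relevance(W), [1.0, 0.25])

    def test_row_permutation_invariant(self, rng):
        W = rng.standard_normal((3, 5))
        np.testing.assert_allclose(relevance(W), relevance(W[::-1]))

    def test_zero_projection_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            rel = relevance(np.zeros((2, 3)))
        np.testing.assert_array_equal(rel, np.zeros(3))

    def test_group_aggregation(self):
        rel = np.array([1.0, 0.5, 0.1, 0.3])
        out = group_relevance(rel, {"a": [0, 1], "b": [2, 3]})
        assert out == {"a": pytest.approx(0.75), "b": pytest.approx(0.2)}


def test_scale_normalization_improves_heldout_alignment():
    """Holding the median-heuristic bandwidth fixed during the ascent should
    generalize better: the free-scale ascent can inflate training alignment
    by shrinking the effective bandwidth (memorization), which a held-out
    alignment evaluation exposes."""
    from ckainit import SyntheticSpec, fit_scaler, generate

    spec = SyntheticSpec(n_per_class=(200, 200, 200), seed=0)
    ds = generate(spec)
    train = np.arange(ds.t.size) % 3 != 0
    sc = fit_scaler(ds.X[train])
    X_tr, X_te = sc.transform(ds.X[train]), sc.transform(ds.X[~train])
    t_tr, t_te = ds.t[train], ds.t[~train]
    rho_te = {}
    for constrained in (True, False):
        cfg = OptimizerConfig(seed=0, max_iter=60, normalize_scale=constrained)
        model = fit_cka_projection(X_tr, t_tr, 14, cfg)
        rho_te[constrained] = cka_objective(model.W, X_te, t_te)
    assert rho_te[True] > rho_te[False]


def test_relevance_recovery_over_seeds():
    """With 10 informative of 50 features at effect size 1.5, the top-10
    relevance ranking recovers them with mean precision >= 0.8 over 20 seeds."""
    from ckainit import SyntheticSpec, fit_scaler, generate

    precisions = []
    for seed in range(20):
        spec = SyntheticSpec(
            group_sizes={"G": 50},
            n_per_class=(80, 80, 80),
            informative_features=tuple(range(10)),
            effect_size=1.5,
            seed=seed,
        )
        ds = generate(spec)
        Xs = fit_scaler(ds.X).transform(ds.X)
        model = fit_cka_projection(Xs, ds.t, 10, OptimizerConfig(seed=seed, max_iter=60))
        top = set(top_k_features(model.relevance, 10).tolist())
        precisions.append(len(top & set(range(10))) / 10)
    assert np.mean(precisions) >= 0.8
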