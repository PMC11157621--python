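import numpy as np
import pytest

from mvmanifold import (
    OptimiserConfig,
    high_dim_affinities,
    kl_divergence,
    low_dim_affinities,
    tsne_embed,
)
from mvmanifold.metrics import cluster_accuracy, kmeans_labels
from mvmanifold.tsne import _descend, _pairwise_sq_dists


def grid_scan_affinities(X, perplexity):
    """Independent oracle: scan sigma on a fine grid per point, evaluate the
    Gaussian conditionals directly and symmetrise."""
    X = np.asarray(X, float)
    n = X.shape[0]
    D = _pairwise_sq_dists(X)
    P = np.zeros((n, n))
    for i in range(n):
        best, best_err = None, np.inf
        for sigma in np.logspace(-3, 3, 20001):
            w = np.exp(-D[i] / (2 * sigma**2))
            w[i] = 0.0
            if w.sum() == 0:
                continue
            p = w / w.sum()
            nz = p[p > 0]
            perp = 2.0 ** (-(nz * np.log2(nz)).sum())
            if abs(perp - perplexity) < best_err:
                best_err, best = abs(perp - perplexity), p
        P[i] = best
    return (P + P.T) / (2 * n)


class TestHighDimAffinities:
    def test_two_points_forced_half(self):
        # a single neighbour forces p_{j|i} = 1 whatever sigma, so the
        # calibration warns and the joint matrix is 0.5 off-diagonal
        with pytest.warns(RuntimeWarning, match="calibration"):
            P = high_dim_affinities(np.array([[0.0], [5.0]]), perplexity=1.5)
        assert P.probs[0, 1] == pytest.approx(0.5)
        assert P.probs[1, 0] == pytest.approx(0.5)

    def test_equidistant_triangle_uniform(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        P = high_dim_affinities(X, perplexity=2.0)
        off = P.probs[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 6, atol=1e-12)

    def test_matches_grid_scan_oracle(self):
        # perplexity 2 with two neighbours sits at the sigma -> inf limit,
        # so a tight calibration tolerance is needed to match the oracle
        X = np.array([[0.0], [1.0], [3.0]])
        P = high_dim_affinities(X, perplexity=2.0, tol=1e-8)
        np.testing.assert_allclose(
            P.probs, grid_scan_affinities(X, 2.0), atol=1e-4
        )

    def test_matches_grid_scan_oracle_interior(self):
        X = np.array([[0.0], [1.0], [3.0], [6.0]])
        P = high_dim_affinities(X, perplexity=2.0, tol=1e-5)
        np.testing.assert_allclose(
            P.probs, grid_scan_affinities(X, 2.0), atol=1e-4
        )

    def test_joint_sums_to_one_and_symmetric(self, rng):
        X = rng.normal(size=(25, 4))
        P = high_dim_affinities(X, perplexity=8.0)
        assert abs(P.probs.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(P.probs, P.probs.T, atol=1e-15)

    def test_achieved_perplexity_within_tol(self, rng):
        X = rng.normal(size=(30, 3))
        P = high_dim_affinities(X, perplexity=10.0, tol=1e-5)
        D = _pairwise_sq_dists(X)
        for i in range(30):
            w = np.exp(-D[i] / (2 * P.sigmas[i] ** 2))
            w[i] = 0.0
            p = w / w.sum()
            H = -(p[p > 0] * np.log2(p[p > 0])).sum()
            assert abs(2.0**H - 10.0) < 1e-3

    def test_perplexity_bounds_enforced(self, rng):
        with pytest.raises(ValueError):
            high_dim_affinities(rng.normal(size=(5, 2)), perplexity=5.0)


class TestLowDimAffinities:
    def test_two_points(self):
        Q = low_dim_affinities(np.array([[0.0], [9.0]]))
        assert Q.probs[0, 1] == pytest.approx(0.5)

    def test_hand_evaluated_line(self):
        Q = low_dim_affinities(np.array([[0.0], [1.0], [3.0]]))
        assert Q.probs[0, 1] == pytest.approx(0.3125)
        assert Q.probs[0, 2] == pytest.approx(0.0625)
        assert Q.probs[1, 2] == pytest.approx(0.125)

    def test_duplicate_points_allowed(self):
        Q = low_dim_affinities(np.array([[0.0], [0.0], [2.0]]))
        assert np.isfinite(Q.probs).all() and abs(Q.probs.sum() - 1) < 1e-12


class TestKLDivergence:
    def test_identity_zero(self, rng):
        p = np.abs(rng.normal(size=(4, 4)))
        np.fill_diagonal(p, 0)
        p /= p.sum()
        assert kl_divergence(p, p) == pytest.approx(0.0)

    def test_hand_value_two_outcomes(self):
        P = np.array([[0.0, 0.7], [0.3, 0.0]])
        Q = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert kl_divergence(P, Q) == pytest.approx(0.08228, abs=1e-5)

    def test_nonnegative_and_zero_iff_equal(self, rng):
        p = np.abs(rng.normal(size=(5, 5)))
        np.fill_diagonal(p, 0)
        p /= p.sum()
        q = p.copy()
        q[0, 1] += 0.01
        q[1, 0] -= 0.005
        q /= q.sum()
        assert kl_divergence(p, q) > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence(np.zeros((3, 3)), np.zeros((4, 4)))


class TestTsneEmbed:
    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(6, 3))
        Y = rng.normal(size=(6, 2))
        P = high_dim_affinities(X, 3.0).probs

        def cost(yflat):
            return kl_divergence(P, low_dim_affinities(yflat.reshape(6, 2)).probs)

        num = 1.0 / (1.0 + _pairwise_sq_dists(Y))
        np.fill_diagonal(num, 0.0)
        Q = num / num.sum()
        PQ = (P - Q) * num
        grad = 4.0 * (np.diag(PQ.sum(1)) @ Y - PQ @ Y)
        eps, y0 = 1e-6, Y.ravel()
        fd = np.array(
            [
                (cost(y0 + eps * np.eye(12)[i]) - cost(y0 - eps * np.eye(12)[i]))
                / (2 * eps)
                for i in range(12)
            ]
        )
        assert np.abs(grad.ravel() - fd).max() < 1e-5

    def test_separates_two_blobs(self, two_blob_matrix):
        X, labels = two_blob_matrix
        e = tsne_embed(X, 10.0, OptimiserConfig(seed=0))
        pred = kmeans_labels(e, 2, seed=0)
        assert cluster_accuracy(labels, pred) == 1.0

    def test_deterministic_given_seed(self, two_blob_matrix):
        X, _ = two_blob_matrix
        e1 = tsne_embed(X, 10.0, OptimiserConfig(seed=3, iterations=120))
        e2 = tsne_embed(X, 10.0, OptimiserConfig(seed=3, iterations=120))
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_cost_non_increasing_plain_descent(self, rng):
        X = rng.normal(size=(15, 3))
        P = high_dim_affinities(X, 5.0).probs
        cfg = OptimiserConfig(
            iterations=200,
            learning_rate=1.0,
            momentum_schedule=(0.0, 0.0, 0),
            early_exaggeration=(1.0, 0),
            use_gains=False,
            seed=0,
        )
        _, _, kls, _, _ = _descend(P[None], np.array([1.0]), 2, cfg)
        costs = kls[:, 0]
        assert np.all(np.diff(costs) <= 1e-12)

    def test_stop_tol_halts_early(self, two_blob_matrix):
        X, _ = two_blob_matrix
        e = tsne_embed(X, 10.0, OptimiserConfig(seed=0, stop_tol=1e-7))
        assert e.iterations_run < 1000
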