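import numpy as np
import pytest

from pmgae.features import SimilarityMatrix
from pmgae.fusion import (
    build_node_features,
    dual_standardize,
    sae_input_profile,
    sae_reduce,
    snf_fuse,
    snf_local_affinity,
    snf_weight_matrix,
)


def _sim(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or tuple(f"n{i}" for i in range(values.shape[0]))
    return SimilarityMatrix(tuple(ids), values)


def _random_sim(rng, n):
    v = rng.random((n, n)) * 0.8 + 0.1
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return _sim(v)


class TestWeightMatrix:
    def test_diagonal_is_half(self):
        rng = np.random.default_rng(0)
        P = snf_weight_matrix(_random_sim(rng, 8))
        np.testing.assert_allclose(np.diag(P), 0.5)

    def test_two_node_uniform(self):
        P = snf_weight_matrix(_sim([[1.0, 1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(P, [[0.5, 0.5], [0.5, 0.5]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        P = snf_weight_matrix(_random_sim(rng, 10))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_isolated_row_named_in_error(self):
        v = np.eye(3)
        with pytest.raises(ValueError, match="n1"):
            snf_weight_matrix(_sim(v, ("n0", "n1", "n2")))


class TestLocalAffinity:
    def test_full_neighborhood_uniform_similarity(self):
        n = 5
        v = np.ones((n, n))
        L = snf_local_affinity(_sim(v), K=n - 1)
        expected = (np.ones((n, n)) - np.eye(n)) / (n - 1)
        np.testing.assert_allclose(L, expected)

    def test_top1_neighbor(self):
        v = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.3], [0.2, 0.3, 1.0]])
        L = snf_local_affinity(_sim(v), K=1)
        np.testing.assert_allclose(L[0], [0, 1, 0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        S = _random_sim(rng, 9)
        for K in (1, 3, 8):
            L = snf_local_affinity(S, K)
            np.testing.assert_allclose(L.sum(axis=1), 1.0, atol=1e-12)

    def test_k_out_of_range(self):
        rng = np.random.default_rng(3)
        S = _random_sim(rng, 4)
        for K in (0, 4):
            with pytest.raises(ValueError):
                snf_local_affinity(S, K)


def _one_round_oracle(views, K):
    """Hand-rolled single cross-diffusion round, element-wise loops only."""
    n = views[0].values.shape[0]
    n_views = len(views)

    def weight(S):
        P = np.zeros((n, n))
        for i in range(n):
            off = sum(S[i, k] for k in range(n) if k != i)
            for j in range(n):
                P[i, j] = 0.5 if i == j else S[i, j] / (2 * off)
        return P

    def local(S):
        L = np.zeros((n, n))
        for i in range(n):
            nbrs = sorted((j for j in range(n) if j != i),
                          key=lambda j: (-S[i, j], j))[:K]
            tot = sum(S[i, j] for j in nbrs)
            for j in nbrs:
                L[i, j] = S[i, j] / tot
        return L

    P = [weight(S.values) for S in views]
    L = [local(S.values) for S in views]
    out = []
    for v in range(n_views):
        others = np.zeros((n, n))
        for k in range(n_views):
            if k != v:
                others += P[k]
        others /= n_views - 1
        upd = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                upd[i, j] = sum(
                    L[v][i, a] * others[a, b] * L[v][j, b]
                    for a in range(n) for b in range(n)
                )
        renorm = np.zeros((n, n))
        for i in range(n):
            off = sum(upd[i, k] for k in range(n) if k != i)
            for j in range(n):
                renorm[i, j] = 0.5 if i == j else upd[i, j] / (2 * off)
        out.append((renorm + renorm.T) / 2)
    fused = sum(out) / n_views
    fused = (fused + fused.T) / 2
    np.fill_diagonal(fused, 1.0)
    return np.clip(fused, 0, 1)


class TestSnfFuse:
    def test_zero_iterations_identical_views_returns_weight_matrix(self):
        rng = np.random.default_rng(4)
        S = _random_sim(rng, 6)
        fused = snf_fuse([S, S, S], K=3, t_max=0)
        P = snf_weight_matrix(S)
        P = (P + P.T) / 2  # the final symmetrization still applies
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(fused.values[off], P[off], atol=1e-12)
        np.testing.assert_allclose(np.diag(fused.values), 1.0)

    def test_one_iteration_matches_hand_rolled_oracle(self):
        rng = np.random.default_rng(5)
        views = [_random_sim(rng, 4) for _ in range(2)]
        fused = snf_fuse(views, K=2, t_max=1, tol=0.0)
        np.testing.assert_allclose(fused.values, _one_round_oracle(views, K=2),
                                   atol=1e-12)

    def test_output_invariants(self):
        rng = np.random.default_rng(6)
        views = [_random_sim(rng, 10) for _ in range(3)]
        fused = snf_fuse(views, K=4, t_max=20)
        v = fused.values
        np.testing.assert_allclose(v, v.T, atol=1e-9)
        assert v.min() >= 0
        np.testing.assert_allclose(np.diag(v), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        n = 8
        raw = [_random_sim(rng, n) for _ in range(3)]
        perm = rng.permutation(n)
        ids = raw[0].ids
        permuted = [
            SimilarityMatrix(tuple(ids[i] for i in perm),
                             S.values[np.ix_(perm, perm)])
            for S in raw
        ]
        f1 = snf_fuse(raw, K=3, t_max=5)
        f2 = snf_fuse(permuted, K=3, t_max=5)
        np.testing.assert_allclose(f2.values, f1.values[np.ix_(perm, perm)],
                                   atol=1e-10)

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(8)
        A = _random_sim(rng, 4)
        B = SimilarityMatrix(("w", "x", "y", "z"), A.values)
        with pytest.raises(ValueError, match="mismatch"):
            snf_fuse([A, B])

    def test_single_view_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            snf_fuse([_random_sim(rng, 4)])


class TestSaeReduce:
    def test_output_shape(self):
        rng = np.random.default_rng(0)
        codes = sae_reduce(rng.random((40, 40)), out_dim=8, seed=1, epochs=20)
        assert codes.shape == (40, 8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 30))
        a = sae_reduce(X, out_dim=5, seed=7, epochs=15)
        b = sae_reduce(X, out_dim=5, seed=7, epochs=15)
        np.testing.assert_array_equal(a, b)

    def test_training_reduces_reconstruction_loss(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 50))
        _, losses = sae_reduce(X, out_dim=10, seed=3, epochs=100, return_loss=True)
        assert losses[-1] < losses[0]

    def test_out_dim_too_large_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            sae_reduce(rng.random((10, 10)), out_dim=10, seed=0)

    def test_linear_sae_recovers_low_rank_input(self):
        # sanity limit: a linear auto-encoder with a wide-enough bottleneck
        # can reconstruct a low-rank matrix almost perfectly
        rng = np.random.default_rng(4)
        B = rng.random((20, 3))
        X = B @ rng.random((3, 20)) * 0.5
        _, losses = sae_reduce(X, out_dim=10, seed=5, epochs=400,
                               activation="identity", return_loss=True)
        assert losses[-1] < 0.05 * losses[0]

    def test_input_profile_zeroes_diagonal_and_scales(self):
        rng = np.random.default_rng(5)
        S = _random_sim(rng, 6)
        M = sae_input_profile(S)
        assert np.diag(M).sum() == 0.0
        assert M.max() == pytest.approx(1.0)


class TestDualStandardize:
    def test_symmetric_two_point_column_is_fixed_point(self):
        M = np.array([[-1.0], [1.0]])
        out = dual_standardize(M)
        np.testing.assert_allclose(out, M)
        np.testing.assert_allclose(dual_standardize(out), out)

    def test_constant_column_all_zeros(self):
        M = np.array([[2.0, 5.0], [2.0, 5.0], [2.0, 5.0]])
        np.testing.assert_array_equal(dual_standardize(M), 0.0)

    def test_hand_computed_column(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        mu, sigma = x.mean(), x.std()
        med = np.median(x)
        q1, q3 = np.percentile(x, [25, 75])
        expected = ((x - mu) / sigma + (x - med) / (q3 - q1)) / 2
        np.testing.assert_allclose(dual_standardize(x[:, None]).ravel(), expected)

    def test_commutes_with_row_permutation(self):
        rng = np.random.default_rng(6)
        M = rng.random((9, 4))
        perm = rng.permutation(9)
        np.testing.assert_allclose(dual_standardize(M[perm]),
                                   dual_standardize(M)[perm], atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            dual_standardize(np.array([[1.0, 2.0]]))


class TestBuildNodeFeatures:
    def test_stacks_preserving_order(self):
        PS = np.arange(6).reshape(2, 3).astype(float)
        MS = np.array([[9.0, 9.0, 9.0]])
        X = build_node_features(PS, MS)
        assert X.shape == (3, 3)
        np.testing.assert_array_equal(X[:2], PS)
        np.testing.assert_array_equal(X[2], MS[0])

    def test_column_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_node_features(np.zeros((2, 3)), np.zeros((1, 4)))
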