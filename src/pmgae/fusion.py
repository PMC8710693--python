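"""Similarity network fusion, auto-encoder reduction, and feature stacking.

The three similarity views per node set are merged by non-linear
cross-diffusion: each view's full-kernel weight matrix is repeatedly pushed
through its own KNN-restricted local transition matrix while averaging over
the *other* views, which amplifies similarity supported by several views and
washes out view-specific noise.  The fused profile is then compressed with a
stacked auto-encoder, standardised twice (z-score and robust), and the two
node sets are stacked into a single node feature matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from pmgae.features import SimilarityMatrix


def snf_weight_matrix(S: SimilarityMatrix) -> np.ndarray:
    """Full-kernel transition matrix: off-diagonal mass halved, diagonal 1/2.

    P(i,j) = S(i,j) / (2 * sum_{k != i} S(i,k)) for i != j, P(i,i) = 1/2,
    so every row sums to exactly 1.
    """
    v = S.values
    off_sums = v.sum(axis=1) - np.diag(v)
    dead = np.flatnonzero(off_sums <= 0)
    if dead.size:
        raise ValueError(
            f"node(s) {[S.ids[i] for i in dead]} have no off-diagonal similarity mass"
        )
    P = v / (2.0 * off_sums[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def snf_local_affinity(S: SimilarityMatrix, K: int) -> np.ndarray:
    """KNN-restricted row-stochastic transition matrix.

    Each row keeps only its K most similar neighbours (self excluded) and is
    renormalised over them; everything else, including the diagonal, is 0.
    """
    v = S.values
    n = v.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K={K} out of range [1, {n - 1}]")
    masked = v.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable top-K: ties broken by lower index
    order = np.argsort(-masked, axis=1, kind="stable")[:, :K]
    L = np.zeros_like(v)
    rows = np.repeat(np.arange(n), K)
    L[rows, order.ravel()] = v[rows, order.ravel()]
    row_sums = L.sum(axis=1, keepdims=True)
    L = np.divide(L, row_sums, out=np.zeros_like(L), where=row_sums > 0)
    return L


def snf_fuse(
    S_list: Sequence[SimilarityMatrix],
    K: int | None = None,
    t_max: int = 20,
    tol: float = 1e-6,
) -> SimilarityMatrix:
    """Cross-diffusion fusion of n >= 2 similarity views over shared ids.

    Each round updates every view v as  P_v <- L_v (mean of other views) L_v^T
    followed by symmetrisation; iteration stops after ``t_max`` rounds or when
    the largest entry change across views drops below ``tol``.  The result is
    the mean of the final view matrices with the diagonal set to 1.
    """
    if len(S_list) < 2:
        raise ValueError("fusion needs at least two similarity views")
    ids = S_list[0].ids
    for S in S_list[1:]:
        if S.ids != ids:
            raise ValueError("similarity views have mismatched ids")
    n_views = len(S_list)
    n = len(ids)
    if K is None:
        K = min(20, n - 1)
    P = [snf_weight_matrix(S) for S in S_list]
    L = [snf_local_affinity(S, K) for S in S_list]
    for _ in range(t_max):
        total = sum(P)
        new = []
        for v in range(n_views):
            others = (total - P[v]) / (n_views - 1)
            upd = L[v] @ others @ L[v].T
            # re-apply the weight normalisation (the standard SNF convention):
            # keeps each status matrix row-stochastic with diagonal 1/2
            off = upd.sum(axis=1) - np.diag(upd)
            off = np.where(off > 0, off, 1.0)
            upd = upd / (2.0 * off[:, None])
            np.fill_diagonal(upd, 0.5)
            new.append((upd + upd.T) / 2.0)
        delta = max(np.abs(new[v] - P[v]).max() for v in range(n_views))
        P = new
        if delta < tol:
            break
    fused = sum(P) / n_views
    fused = (fused + fused.T) / 2.0
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(ids, np.clip(fused, 0.0, 1.0))


def sae_input_profile(S_fused: SimilarityMatrix) -> np.ndarray:
    """Prepare a fused similarity matrix for auto-encoder compression.

    The unit diagonal is constant by construction and carries no
    information, while the off-diagonal diffusion weights are two orders of
    magnitude smaller; a squared-error reconstruction objective on the raw
    matrix would spend nearly all its capacity on the diagonal.  The
    diagonal is therefore zeroed and the profile rescaled to unit maximum.
    """
    M = S_fused.values.copy()
    np.fill_diagonal(M, 0.0)
    peak = M.max()
    return M / peak if peak > 0 else M


def sae_reduce(
    S_fused: SimilarityMatrix | np.ndarray,
    out_dim: int = 128,
    seed: int = 0,
    hidden: int = 256,
    epochs: int = 200,
    activation: str = "relu",
    return_loss: bool = False,
):
    """Compress similarity-profile rows with a symmetric stacked auto-encoder.

    Architecture n -> hidden -> out_dim -> hidden -> n trained with
    squared-error reconstruction loss (Adam, fixed epoch budget); returns the
    bottleneck activations per row.  Deterministic for a given seed.
    """
    X = S_fused.values if isinstance(S_fused, SimilarityMatrix) else np.asarray(S_fused, float)
    n = X.shape[0]
    if out_dim >= n:
        raise ValueError(f"out_dim={out_dim} must be smaller than n={n}")
    model = MLPRegressor(
        hidden_layer_sizes=(hidden, out_dim, hidden),
        activation=activation,
        solver="adam",
        max_iter=epochs,
        random_state=int(seed),
        tol=0.0,  # run the full epoch budget
        n_iter_no_change=epochs,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, X)
    codes = _bottleneck(model, X, activation)
    if return_loss:
        return codes, list(model.loss_curve_)
    return codes


def _bottleneck(model: MLPRegressor, X: np.ndarray, activation: str) -> np.ndarray:
    """Forward pass through the encoder half of a fitted symmetric MLP."""
    h = X
    for W, b in zip(model.coefs_[:2], model.intercepts_[:2]):
        h = h @ W + b
        if activation == "relu":
            h = np.maximum(h, 0.0)
        elif activation == "tanh":
            h = np.tanh(h)
        elif activation != "identity":
            raise ValueError(f"unsupported activation {activation!r}")
    return h


def dual_standardize(M: np.ndarray) -> np.ndarray:
    """Mean of per-column z-scores and robust (median/IQR) scores.

    z uses the population standard deviation; the robust score uses
    IQR = Q3 - Q1 with linearly interpolated quantiles.  Degenerate columns
    (sigma = 0 or IQR = 0) contribute 0 for the affected score.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("dual_standardize needs a matrix with at least 2 rows")
    mu = M.mean(axis=0)
    sigma = M.std(axis=0)  # population (ddof=0)
    med = np.median(M, axis=0)
    q1, q3 = np.percentile(M, [25, 75], axis=0)
    iqr = q3 - q1
    z = np.where(sigma > 0, (M - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    r = np.where(iqr > 0, (M - med) / np.where(iqr > 0, iqr, 1.0), 0.0)
    return (z + r) / 2.0


def build_node_features(PS2: np.ndarray, MS2: np.ndarray) -> np.ndarray:
    """Stack standardised pseudogene and miRNA features, pseudogene rows first."""
    PS2 = np.atleast_2d(np.asarray(PS2, float))
    MS2 = np.atleast_2d(np.asarray(MS2, float))
    if PS2.shape[1] != MS2.shape[1]:
        raise ValueError(
            f"feature widths differ: {PS2.shape[1]} vs {MS2.shape[1]}"
        )
    return np.vstack([PS2, MS2])
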