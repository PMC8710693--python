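"""Graph auto-encoder over the bipartite association graph.

The encoder is a two-layer graph convolution Z = A_norm ReLU(A_norm X W0) W1
on the symmetric block adjacency [[0, PMA], [PMA^T, 0]]; the inner-product
decoder sigmoid(Z Z^T) is used only to form the reconstruction loss during
training — prediction consumes the embeddings Z directly.

Training is full-batch gradient descent (Adam) on the binary cross-entropy
between the decoder output and the adjacency, with an optional positive-class
weight to counter the extreme sparsity of real association graphs.  The
implementation is pure numpy with hand-derived gradients, which keeps a
desk-scale graph (a few hundred nodes) training in seconds and makes runs
bit-reproducible from a seed.

Self-loops are added before symmetric normalisation (the standard GCN
renormalisation): without them the normalisation is undefined for isolated
nodes and a node's own features never reach its embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pmgae.features import AssociationMatrix
from pmgae.io_formats import RunConfig


@dataclass
class BipartiteGraph:
    """Block adjacency of the bipartite association graph plus node features."""

    node_ids: tuple[str, ...]  # pseudogenes first, then miRNAs
    n_pseudogenes: int
    A: np.ndarray        # (n, n) binary, zero diagonal, zero within-set blocks
    A_norm: np.ndarray   # D^{-1/2} (A + I) D^{-1/2}
    X: np.ndarray        # (n, d) node features


@dataclass
class GAEModel:
    """Trained encoder weights, final embeddings, and the loss trajectory."""

    W0: np.ndarray
    W1: np.ndarray
    Z: np.ndarray
    loss_history: list[float] = field(default_factory=list)


def build_adjacency(PMA: AssociationMatrix, X: np.ndarray | None = None) -> BipartiteGraph:
    """Assemble A = [[0, PMA], [PMA^T, 0]] and its normalised form."""
    m = PMA.values
    n_p, n_m = m.shape
    n = n_p + n_m
    A = np.zeros((n, n))
    A[:n_p, n_p:] = m
    A[n_p:, :n_p] = m.T
    if X is None:
        X = np.eye(n)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != n:
        raise ValueError(f"feature rows {X.shape[0]} != node count {n}")
    return BipartiteGraph(
        node_ids=tuple(PMA.row_ids) + tuple(PMA.col_ids),
        n_pseudogenes=n_p,
        A=A,
        A_norm=normalize_adjacency(A),
        X=X,
    )


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalised adjacency D^{-1/2} (A + I) D^{-1/2}."""
    A = np.asarray(A, dtype=float)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def encode(X: np.ndarray, A_norm: np.ndarray, W0: np.ndarray, W1: np.ndarray) -> np.ndarray:
    """Two-layer GCN encoder: Z = A_norm ReLU(A_norm X W0) W1."""
    return A_norm @ relu(A_norm @ X @ W0) @ W1


def decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder: edge probabilities sigmoid(Z Z^T)."""
    return sigmoid(Z @ Z.T)


def reconstruction_loss(A: np.ndarray, A_hat: np.ndarray, pos_weight: float = 1.0) -> float:
    """Weighted binary cross-entropy over every adjacency entry.

    L = -(1/N) sum[ w y log(yhat) + (1-y) log(1-yhat) ], with predictions
    clamped to [eps, 1-eps].  pos_weight=1 is the unweighted form.
    """
    eps = 1e-15
    A = np.asarray(A, float)
    P = np.clip(np.asarray(A_hat, float), eps, 1.0 - eps)
    N = A.size
    terms = pos_weight * A * np.log(P) + (1.0 - A) * np.log(1.0 - P)
    return float(-terms.sum() / N)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def train_gae(
    graph: BipartiteGraph,
    config: RunConfig,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> GAEModel:
    """Train the GAE by full-batch Adam on the reconstruction loss.

    Weights use seed-controlled Glorot-uniform initialisation (or the given
    ``init`` pair); the positive-class weight defaults to #zeros/#ones of the
    adjacency.  Raises if the loss ever becomes non-finite.
    """
    A, A_norm, X = graph.A, graph.A_norm, graph.X
    h0, h1 = config.gae_hidden
    rng = np.random.default_rng(config.stage_seed("gae"))
    if init is not None:
        W0, W1 = np.array(init[0], float), np.array(init[1], float)
    else:
        W0 = _glorot(rng, X.shape[1], h0)
        W1 = _glorot(rng, h0, h1)
    n_ones = A.sum()
    if config.gae_pos_weight is not None:
        w = float(config.gae_pos_weight)
    else:
        w = float((A.size - n_ones) / n_ones) if n_ones > 0 else 1.0
    N = A.size
    AX = A_norm @ X  # constant across epochs

    # Adam state
    lr, b1, b2, eps_adam = config.gae_lr, 0.9, 0.999, 1e-8
    m = [np.zeros_like(W0), np.zeros_like(W1)]
    v = [np.zeros_like(W0), np.zeros_like(W1)]

    history: list[float] = []
    for t in range(1, config.gae_epochs + 1):
        H_pre = AX @ W0
        H = relu(H_pre)
        M = A_norm @ H
        Z = M @ W1
        S = Z @ Z.T
        P = sigmoid(S)
        loss = reconstruction_loss(A, P, pos_weight=w)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"GAE loss became non-finite at epoch {t}; "
                "reduce the learning rate or check the inputs"
            )
        history.append(loss)

        # dL/dS for weighted BCE: (1-y) sigma(s) - w y (1 - sigma(s)), / N
        G = ((1.0 - A) * P - w * A * (1.0 - P)) / N
        dZ = (G + G.T) @ Z
        dW1 = M.T @ dZ
        dM = dZ @ W1.T
        dH = A_norm @ dM          # A_norm is symmetric
        dH_pre = dH * (H_pre > 0)
        dW0 = AX.T @ dH_pre

        for i, (W, g) in enumerate(((W0, dW0), (W1, dW1))):
            m[i] = b1 * m[i] + (1 - b1) * g
            v[i] = b2 * v[i] + (1 - b2) * g * g
            m_hat = m[i] / (1 - b1**t)
            v_hat = v[i] / (1 - b2**t)
            W -= lr * m_hat / (np.sqrt(v_hat) + eps_adam)

    Z = encode(X, A_norm, W0, W1)
    return GAEModel(W0=W0, W1=W1, Z=Z, loss_history=history)
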