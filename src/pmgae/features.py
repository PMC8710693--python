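"""Per-node-set similarity profiles from raw node attributes.

miRNAs are described by k-mer frequency vectors of their sequences,
pseudogenes by min-max-normalised tissue expression.  Three similarity
measures (generalised Jaccard, cosine, Pearson) are computed per node set;
exact zeros are then replaced with the Gaussian interaction-profile (GIP)
kernel computed from the binary association matrix.

Signed measures (cosine, Pearson) are rescaled s -> (s+1)/2 so all three
share the [0,1] range the fusion and zero-filling stages assume.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from pmgae.io_formats import AssociationTable, ExpressionTable, SequenceRecord

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric node-by-node similarity with unit diagonal in [0,1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"similarity shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity diagonal is not 1")
        if v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL:
            raise ValueError("similarity entries outside [0,1]")


@dataclass(frozen=True)
class KmerProfile:
    """Row-stochastic k-mer frequency vectors, 4^k columns in lexicographic order."""

    ids: tuple[str, ...]
    k: int
    vectors: np.ndarray  # (n, 4^k)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary pseudogene x miRNA incidence matrix."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("association matrix shape inconsistent with ids")
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")


def association_matrix(
    table: AssociationTable,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Binary incidence matrix of an association table in canonical order."""
    rows = tuple(row_order) if row_order is not None else tuple(sorted(table.row_universe))
    cols = tuple(col_order) if col_order is not None else tuple(sorted(table.col_universe))
    ridx = {r: i for i, r in enumerate(rows)}
    cidx = {c: j for j, c in enumerate(cols)}
    m = np.zeros((len(rows), len(cols)))
    for r, c in table.pairs:
        m[ridx[r], cidx[c]] = 1.0
    return AssociationMatrix(rows, cols, m)


def kmer_order(k: int) -> list[str]:
    """All 4^k k-mers over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in product("ACGU", repeat=k)]


def kmer_frequencies(record: SequenceRecord, k: int = 3) -> np.ndarray:
    """Frequency of each k-mer: count(w) / (L - k + 1).

    The vector has 4^k entries in lexicographic k-mer order and sums to 1.
    """
    seq = record.sequence
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        raise ValueError(
            f"sequence {record.id!r} shorter than k={k} ({len(seq)} nt)"
        )
    index = {w: i for i, w in enumerate(kmer_order(k))}
    vec = np.zeros(4**k)
    for i in range(n_windows):
        vec[index[seq[i:i + k]]] += 1.0
    return vec / n_windows


def kmer_profile(records: Sequence[SequenceRecord], k: int = 3) -> KmerProfile:
    ids = tuple(sorted(r.id for r in records))
    by_id = {r.id: r for r in records}
    vectors = np.vstack([kmer_frequencies(by_id[i], k) for i in ids])
    return KmerProfile(ids, k, vectors)


def normalize_expression(table: ExpressionTable) -> ExpressionTable:
    """Per-tissue min-max scaling to [0,1]; constant tissues map to 0."""
    v = table.values
    if v.min() < 0:
        raise ValueError("expression values must be non-negative")
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ExpressionTable(table.row_ids, table.col_ids, out)


def _finalize(ids: Sequence[str], values: np.ndarray) -> SimilarityMatrix:
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(tuple(ids), values)


def jaccard_similarity(M: np.ndarray, ids: Sequence[str]) -> SimilarityMatrix:
    """Generalised (Ruzicka) Jaccard: sum(min) / sum(max), rows as samples.

    Reduces to set Jaccard on binary input.  A pair of all-zero rows has
    similarity 1 (identical supports).
    """
    M = np.asarray(M, dtype=float)
    if M.min() < 0:
        raise ValueError("Jaccard similarity undefined for negative values")
    # pairwise sum-of-min / sum-of-max via broadcasting
    mins = np.minimum(M[:, None, :], M[None, :, :]).sum(axis=2)
    maxs = np.maximum(M[:, None, :], M[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 1.0)
    return _finalize(ids, S)


def cosine_similarity(M: np.ndarray, ids: Sequence[str]) -> SimilarityMatrix:
    """Cosine of row vectors, rescaled (s+1)/2; zero rows get raw 0 off-diagonal."""
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = M / safe[:, None]
    S = unit @ unit.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    return _finalize(ids, (S + 1.0) / 2.0)


def pearson_similarity(M: np.ndarray, ids: Sequence[str]) -> SimilarityMatrix:
    """Pearson correlation of rows, rescaled (s+1)/2; zero-variance rows -> raw 0."""
    M = np.asarray(M, dtype=float)
    centered = M - M.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(sd > 0, sd, 1.0)
    unit = centered / safe[:, None]
    S = unit @ unit.T
    S[sd == 0, :] = 0.0
    S[:, sd == 0] = 0.0
    return _finalize(ids, (S + 1.0) / 2.0)


def gip_kernel(A: AssociationMatrix, axis: str = "rows") -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over association profiles.

    G(i,j) = exp(-gamma * ||IP(i) - IP(j)||^2) with the bandwidth normalised
    by the mean squared profile norm, gamma = 1 / mean_i ||IP(i)||^2 (gamma=1
    when every profile is empty).
    """
    if axis == "rows":
        profiles, ids = A.values, A.row_ids
    elif axis == "cols":
        profiles, ids = A.values.T, A.col_ids
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    gamma = 1.0 / mean_sq if mean_sq > 0 else 1.0
    sq_dists = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    G = np.exp(-gamma * np.maximum(sq_dists, 0.0))
    return _finalize(ids, G)


def fill_zeros(S: SimilarityMatrix, G: SimilarityMatrix) -> SimilarityMatrix:
    """Replace exact zeros of S with the corresponding GIP kernel entries."""
    if S.ids != G.ids:
        raise ValueError("similarity and GIP kernel ids differ")
    out = np.where(S.values > 0, S.values, G.values)
    return _finalize(S.ids, out)
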