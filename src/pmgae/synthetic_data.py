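"""Seeded synthetic fixtures with planted bipartite structure.

The generator draws a latent factor per node and derives all three
observable layers from it, so that expression similarity (pseudogenes),
3-mer-profile similarity (miRNAs), and the edge pattern all reflect the same
geometry and the pipeline has a recoverable signal:

Latent vectors are drawn from ``latent_dim`` cluster archetypes (a unit
basis vector plus isotropic noise), emulating the modularity of real ceRNA
data — miRNA families share target sets and pseudogenes fall into
co-expressed modules — so similarity profiles carry block structure rather
than a diffuse bilinear signal:

* pseudogene expression = softplus of a linear map of its latent vector plus
  Gaussian noise;
* miRNA sequences oversample a set of designated "motif" 3-mers with weights
  tied to the latent vector (``motif_strength`` mixes this with a uniform
  background);
* an edge (i, j) is Bernoulli with probability sigmoid(a u_i . v_j + b),
  with the offset b calibrated so the expected edge count matches
  ``n_edges``;
  a fraction ``edge_noise`` of realised edges is then rewired to uniformly
  random empty cells.

``decouple_edges=True`` severs the edge layer from the latent geometry
entirely: edges become i.i.d. Bernoulli at the target density.  Together
with ``motif_strength=0`` this is the null-signal control — neither node
attributes nor the graph itself carry recoverable structure.  (A merely
latent-decoupled but still low-rank graph would not be a null: its internal
structure is learnable from training folds by the graph stage alone.)

Default scale (120 x 60, 500 edges, ~7% density) keeps a full
cross-validated run desk-sized; ``full_scale()`` returns the 444 x 173 /
1,884-edge geometry of the real curated network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from pmgae.features import kmer_order
from pmgae.io_formats import (
    AssociationTable,
    ExpressionTable,
    SequenceRecord,
    write_edge_list,
    write_expression_tsv,
    write_fasta,
)

SEQ_LENGTH = 60  # nt per synthetic miRNA (20 sampled 3-mers)
CLUSTER_SPREAD = 0.4  # sd of isotropic noise around each cluster archetype
EDGE_SHARPNESS = 4.0  # logistic scale on the latent dot product


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the study conditions of the fixture."""

    n_pseudogenes: int = 120
    n_mirnas: int = 60
    n_tissues: int = 20
    latent_dim: int = 8
    n_edges: int = 500
    edge_noise: float = 0.05
    motif_strength: float = 0.8
    expression_noise: float = 0.1
    decouple_edges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pseudogenes", "n_mirnas", "n_tissues", "latent_dim", "n_edges"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_edges > self.n_pseudogenes * self.n_mirnas:
            raise ValueError("n_edges exceeds the number of cells (density > 1)")
        if not 0 <= self.edge_noise < 0.5:
            raise ValueError("edge_noise must be in [0, 0.5)")
        if not 0 <= self.motif_strength <= 1:
            raise ValueError("motif_strength must be in [0, 1]")


def full_scale(seed: int = 0, **overrides) -> SyntheticSpec:
    """The 444 x 173 / 1,884-edge geometry of the real curated network."""
    base = SyntheticSpec(n_pseudogenes=444, n_mirnas=173, n_edges=1884, seed=seed)
    return replace(base, **overrides)


def _motif_kmers(latent_dim: int, k: int = 3) -> list[str]:
    """latent_dim designated 3-mers, spread evenly through lexicographic order."""
    order = kmer_order(k)
    idx = np.linspace(0, len(order) - 1, latent_dim).astype(int)
    return [order[i] for i in idx]


def _sample_sequence(rng: np.random.Generator, v: np.ndarray, strength: float,
                     motifs: Sequence[str], k: int = 3) -> str:
    order = kmer_order(k)
    base = np.full(len(order), 1.0 / len(order))
    w = np.exp(2.0 * (v - v.max()))
    motif_dist = np.zeros(len(order))
    for m, wi in zip(motifs, w / w.sum()):
        motif_dist[order.index(m)] = wi
    p = (1.0 - strength) * base + strength * motif_dist
    picks = rng.choice(len(order), size=SEQ_LENGTH // k, p=p)
    return "".join(order[i] for i in picks)


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionTable, list[SequenceRecord], AssociationTable, dict]:
    """Generate one fixture; fully determined by ``spec`` (including seed)."""
    rng = np.random.default_rng(spec.seed)
    n_p, n_m, d = spec.n_pseudogenes, spec.n_mirnas, spec.latent_dim
    pg_ids = [f"PG{i:04d}" for i in range(n_p)]
    mi_ids = [f"miR-{j:04d}" for j in range(n_m)]

    U = np.eye(d)[rng.integers(d, size=n_p)] + CLUSTER_SPREAD * rng.standard_normal((n_p, d))
    V = np.eye(d)[rng.integers(d, size=n_m)] + CLUSTER_SPREAD * rng.standard_normal((n_m, d))

    # expression layer
    W = rng.standard_normal((d, spec.n_tissues)) / np.sqrt(d)
    expr = np.logaddexp(0.0, U @ W + spec.expression_noise
                        * rng.standard_normal((n_p, spec.n_tissues)))
    expression = ExpressionTable(tuple(pg_ids), tuple(f"tissue{t:02d}" for t in range(spec.n_tissues)), expr)

    # sequence layer
    motifs = _motif_kmers(d)
    sequences = [
        SequenceRecord(mi_ids[j], _sample_sequence(rng, V[j], spec.motif_strength, motifs))
        for j in range(n_m)
    ]

    # edge layer (optionally decoupled from the attribute latents)
    target = spec.n_edges / (n_p * n_m)
    if spec.decouple_edges:
        probs = np.full((n_p, n_m), target)
    else:
        scores = EDGE_SHARPNESS * U @ V.T
        b = brentq(lambda t: expit(scores + t).mean() - target, -50.0, 50.0)
        probs = expit(scores + b)
    edges = rng.random((n_p, n_m)) < probs

    # rewire a fraction of realised edges to random empty cells
    if spec.edge_noise > 0:
        pos = np.argwhere(edges)
        to_move = pos[rng.random(len(pos)) < spec.edge_noise]
        for i, j in to_move:
            edges[i, j] = False
            empty = np.argwhere(~edges)
            i2, j2 = empty[rng.integers(len(empty))]
            edges[i2, j2] = True

    pairs = tuple((pg_ids[i], mi_ids[j]) for i, j in np.argwhere(edges))
    associations = AssociationTable(pairs, tuple(pg_ids), tuple(mi_ids))
    truth = {
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        "U": U.tolist(),
        "V": V.tolist(),
        "edge_probs": probs.tolist(),
        "n_realized_edges": int(edges.sum()),
        "motif_kmers": motifs,
    }
    return expression, sequences, associations, truth


def write_fixture(
    outputs: tuple[ExpressionTable, list[SequenceRecord], AssociationTable, dict],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write expression.tsv, mirna.fasta, edges.tsv, and truth.json."""
    expression, sequences, associations, truth = outputs
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "sequences": out_dir / "mirna.fasta",
        "edges": out_dir / "edges.tsv",
        "truth": out_dir / "truth.json",
    }
    write_expression_tsv(expression, paths["expression"])
    write_fasta(sequences, paths["sequences"])
    write_edge_list(associations, paths["edges"])
    paths["truth"].write_text(json.dumps(truth) + "\n")
    return paths
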