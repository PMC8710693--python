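"""File formats, domain tables, and the run configuration.

All matrices downstream are indexed by *sorted* id lists (pseudogenes
lexicographic, then miRNAs lexicographic), so file ordering never affects
results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("pmgae")

RNA_ALPHABET = frozenset("ACGU")


class ParseError(ValueError):
    """Malformed input file; carries the offending location when known."""


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence over {A, C, G, U}; T is mapped to U on input."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(expected A/C/G/U, with T accepted on input)"
            )
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class ExpressionTable:
    """Pseudogene expression across tissues: rows = pseudogenes, cols = tissues."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray  # (n_rows, n_cols) float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"expression shape {v.shape} inconsistent with "
                f"{len(self.row_ids)} row ids / {len(self.col_ids)} col ids"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids in expression table")
        if not np.isfinite(v).all():
            raise ValueError("expression table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.col_ids))


@dataclass(frozen=True)
class AssociationTable:
    """Known positive (pseudogene, miRNA) pairs plus the node universes."""

    pairs: tuple[tuple[str, str], ...]
    row_universe: tuple[str, ...]
    col_universe: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate association pairs")
        rows = set(self.row_universe)
        cols = set(self.col_universe)
        for r, c in self.pairs:
            if r not in rows:
                raise ValueError(f"association row id {r!r} not in row universe")
            if c not in cols:
                raise ValueError(f"association col id {c!r} not in col universe")


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of the pipeline, with a single master seed.

    Per-stage seeds are derived deterministically from ``random_seed`` via
    numpy's SeedSequence spawning, so a full run is bit-reproducible.
    """

    k: int = 3
    snf_neighbors: int = 20
    snf_iterations: int = 20
    sae_hidden: int = 256
    sae_dim: int = 128
    sae_epochs: int = 200
    gae_hidden: tuple[int, int] = (64, 32)
    gae_lr: float = 0.001
    gae_epochs: int = 8000
    gae_pos_weight: float | None = None  # None -> (#zeros/#ones) of the adjacency
    xgb_n_estimators: int = 100
    xgb_max_depth: int = 6
    xgb_learning_rate: float = 0.3
    xgb_reg_lambda: float = 1.0
    neg_ratio: int = 1
    cv_folds: int = 5
    mask_test_edges: bool = True
    threshold: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k", "snf_neighbors", "sae_hidden", "sae_dim", "sae_epochs",
                     "gae_epochs", "xgb_n_estimators", "xgb_max_depth", "cv_folds"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.snf_iterations < 0:
            raise ValueError("snf_iterations must be >= 0")
        if self.gae_lr <= 0 or self.xgb_learning_rate <= 0:
            raise ValueError("learning rates must be > 0")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        if len(self.gae_hidden) != 2 or any(h <= 0 for h in self.gae_hidden):
            raise ValueError("gae_hidden must be two positive layer sizes")
        object.__setattr__(self, "gae_hidden", tuple(int(h) for h in self.gae_hidden))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the master seed."""
        child = np.random.SeedSequence([self.random_seed, _stable_hash(stage)])
        return int(child.generate_state(1)[0] % (2**31))

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"config {path}: expected a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"config {path}: unknown keys {sorted(unknown)}")
        if "gae_hidden" in raw:
            raw["gae_hidden"] = tuple(raw["gae_hidden"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["gae_hidden"] = list(self.gae_hidden)
        return d


def _stable_hash(s: str) -> int:
    # Python's hash() is salted per process; use a stable FNV-1a instead.
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read RNA sequences; DNA-style T is normalised to U, order preserved."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("T", "U")
        try:
            records.append(SequenceRecord(rec.id, seq))
        except ParseError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    """Read a TSV with a tissue-name header row and row ids in column one.

    Missing or non-numeric cells are an error: filtering and imputation are
    upstream concerns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row ids {dups}")
    try:
        values = df.to_numpy(dtype=str).astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric or missing cell ({exc})") from exc
    if not np.isfinite(values).all():
        raise ParseError(f"{path}: non-finite cell value")
    return ExpressionTable(tuple(df.index), tuple(df.columns), values)


def read_edge_list(
    path: str | Path,
    row_universe: Sequence[str],
    col_universe: Sequence[str],
) -> AssociationTable:
    """Read a two-column TSV of (pseudogene, miRNA) pairs.

    Duplicates are dropped with a logged warning; ids outside the universes
    are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ParseError(f"{path}: empty edge list")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for r, c in df.itertuples(index=False):
        if (r, c) in seen:
            n_dup += 1
            continue
        seen.add((r, c))
        pairs.append((r, c))
    if n_dup:
        logger.warning("%s: dropped %d duplicate pairs", path, n_dup)
    return AssociationTable(tuple(pairs), tuple(row_universe), tuple(col_universe))


# ---------------------------------------------------------------------------
# writers


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="id")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_edge_list(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r, c in table.pairs:
            fh.write(f"{r}\t{c}\n")


def write_matrix_tsv(ids_rows: Sequence[str], ids_cols: Sequence[str],
                     values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=list(ids_rows), columns=list(ids_cols)).to_csv(
        path, sep="\t", index_label="id"
    )


def read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), list(df.columns), df.to_numpy(dtype=float)


def write_metrics(report, path: str | Path) -> None:
    """Serialise an evaluation report as JSON: per-fold entries plus a mean."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ranking(ranking: Sequence[tuple[str, float]], path: str | Path) -> None:
    """Write (rank, id, score) rows, descending by score."""
    ordered = sorted(ranking, key=lambda t: (-t[1], t[0]))
    with open(path, "w") as fh:
        fh.write("rank\tid\tscore\n")
        for i, (cand, score) in enumerate(ordered, start=1):
            fh.write(f"{i}\t{cand}\t{score:.10g}\n")


def sorted_node_order(
    pseudogene_ids: Iterable[str], mirna_ids: Iterable[str]
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Canonical node order: each set sorted lexicographically."""
    return tuple(sorted(pseudogene_ids)), tuple(sorted(mirna_ids))
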