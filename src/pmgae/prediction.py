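"""Pair-level classification on top of node embeddings.

A (pseudogene, miRNA) pair is represented as the concatenation of the two
node embeddings (pseudogene half first — the relation is directed by role,
so the representation is deliberately asymmetric).  The classifier is a
regularised gradient-boosted tree ensemble (XGBoost) trained on labelled
pairs; its probability output drives both thresholded metrics and rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from xgboost import XGBClassifier

from pmgae.io_formats import RunConfig


@dataclass
class LabeledPairSet:
    """(pseudogene, miRNA) pairs with labels, feature rows, and scores."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    features: np.ndarray
    scores: np.ndarray | None = None


def pair_features(Z: Mapping[str, np.ndarray], pair: tuple[str, str]) -> np.ndarray:
    """Concatenate the two node embeddings, pseudogene half first."""
    p, m = pair
    if p not in Z:
        raise KeyError(f"unknown pseudogene id {p!r}")
    if m not in Z:
        raise KeyError(f"unknown miRNA id {m!r}")
    return np.concatenate([Z[p], Z[m]])


def build_pair_set(
    Z: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
) -> LabeledPairSet:
    feats = np.vstack([pair_features(Z, p) for p in pairs])
    return LabeledPairSet(list(pairs), np.asarray(labels, dtype=int), feats)


def train_classifier(train: LabeledPairSet, seed: int, config: RunConfig | None = None) -> XGBClassifier:
    """Fit the gradient-boosted tree ensemble on a labelled pair set."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    config = config or RunConfig()
    clf = XGBClassifier(
        n_estimators=config.xgb_n_estimators,
        max_depth=config.xgb_max_depth,
        learning_rate=config.xgb_learning_rate,
        reg_lambda=config.xgb_reg_lambda,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
    )
    clf.fit(train.features, train.labels)
    return clf


def predict_scores(classifier: XGBClassifier, pairs: LabeledPairSet) -> np.ndarray:
    """Probability-like score in [0,1] per pair."""
    scores = classifier.predict_proba(pairs.features)[:, 1].astype(float)
    pairs.scores = scores
    return scores


def rank_candidates(
    classifier: XGBClassifier,
    Z: Mapping[str, np.ndarray],
    query_pseudogene: str,
    candidate_mirnas: Sequence[str],
    top_k: int = 15,
) -> list[tuple[str, float]]:
    """Rank candidate miRNAs for one pseudogene by descending score.

    Ties are broken lexicographically by miRNA id, so the ranking is
    invariant to candidate input order.
    """
    if not candidate_mirnas:
        raise ValueError("empty candidate list")
    feats = np.vstack(
        [pair_features(Z, (query_pseudogene, m)) for m in candidate_mirnas]
    )
    scores = classifier.predict_proba(feats)[:, 1]
    ranked = sorted(zip(candidate_mirnas, scores), key=lambda t: (-t[1], t[0]))
    return [(m, float(s)) for m, s in ranked[:top_k]]
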