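"""Cross-validation orchestration, metrics, and the case-study protocol.

Evaluation is the only place the full pipeline is assembled: per split, the
association-derived features (GIP zero-filling, fusion, auto-encoder,
standardisation) and the GAE adjacency are rebuilt from *training* positives
only, so no structure of a test pair ever reaches its feature vector.  The
raw Jaccard / cosine / Pearson similarities depend only on expression and
sequence attributes and are computed once per experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pmgae import features as feat
from pmgae import fusion as fus
from pmgae import gae_embedding as gae
from pmgae import prediction as pred
from pmgae.features import AssociationMatrix, SimilarityMatrix
from pmgae.io_formats import (
    AssociationTable,
    ExpressionTable,
    RunConfig,
    SequenceRecord,
    sorted_node_order,
)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "mcc", "auc", "aupr")


@dataclass
class EvalReport:
    """Per-fold metrics with mean/std aggregates and the generating config."""

    per_fold: list[dict[str, float]]
    config: dict
    seed: int
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {
            k: float(np.mean([f[k] for f in self.per_fold])) for k in METRIC_NAMES
        }
        self.std = {
            k: float(np.std([f[k] for f in self.per_fold])) for k in METRIC_NAMES
        }

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "std": self.std,
            "config": self.config,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# sampling and splitting


def sample_negatives(
    PMA: AssociationMatrix, ratio: int, seed: int
) -> list[tuple[str, str]]:
    """Uniform sample of zero cells, ratio x the number of positive cells."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    zeros = np.argwhere(PMA.values == 0)
    n_pos = int(PMA.values.sum())
    n_need = ratio * n_pos
    if n_need > len(zeros):
        raise ValueError(
            f"requested {n_need} negatives but only {len(zeros)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n_need, replace=False)]
    return [(PMA.row_ids[i], PMA.col_ids[j]) for i, j in chosen]


def kfold_split(
    pairs: Sequence[tuple[str, str]],
    labels: Sequence[int],
    k: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold: positives and negatives each split into k parts.

    Returns (train_idx, test_idx) arrays; test sets are disjoint and cover
    every pair exactly once.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"fewer than k={k} samples of class {cls}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# metrics


def confusion_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / precision / MCC at a threshold.

    Any metric with a zero denominator is reported as 0 with a warning.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    yhat = (s >= threshold).astype(int)
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
            return 0.0
        return num / den

    acc = _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    sen = _ratio(tp, tp + fn, "sensitivity")
    spe = _ratio(tn, tn + fp, "specificity")
    pre = _ratio(tp, tp + fp, "precision")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.warn("mcc: zero denominator, reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return {
        "accuracy": float(acc),
        "sensitivity": float(sen),
        "specificity": float(spe),
        "precision": float(pre),
        "mcc": float(mcc),
    }


def auc_aupr(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, float]:
    """ROC AUC (rank construction, tie-aware) and AUPR (step integration)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for AUC/AUPR")
    s = np.asarray(scores, dtype=float)
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


# ---------------------------------------------------------------------------
# pipeline assembly


@dataclass
class Dataset:
    """The three raw inputs of a full run."""

    expression: ExpressionTable
    sequences: Sequence[SequenceRecord]
    associations: AssociationTable


@dataclass
class _AttributeSimilarities:
    """Association-free similarity views, computed once per experiment."""

    pg_ids: tuple[str, ...]
    mi_ids: tuple[str, ...]
    pg_views: list[SimilarityMatrix]
    mi_views: list[SimilarityMatrix]


def attribute_similarities(dataset: Dataset, config: RunConfig) -> _AttributeSimilarities:
    """Jaccard / cosine / Pearson per node set from expression and k-mers."""
    pg_ids, mi_ids = sorted_node_order(
        dataset.expression.row_ids, [r.id for r in dataset.sequences]
    )
    norm = feat.normalize_expression(dataset.expression)
    expr = norm.to_frame().loc[list(pg_ids)].to_numpy()
    prof = feat.kmer_profile(list(dataset.sequences), k=config.k)
    assert prof.ids == mi_ids
    kmers = prof.vectors
    views = (feat.jaccard_similarity, feat.cosine_similarity, feat.pearson_similarity)
    return _AttributeSimilarities(
        pg_ids=pg_ids,
        mi_ids=mi_ids,
        pg_views=[v(expr, pg_ids) for v in views],
        mi_views=[v(kmers, mi_ids) for v in views],
    )


@dataclass
class FittedModel:
    """A pipeline fitted on one set of training positives."""

    embeddings: dict[str, np.ndarray]
    classifier: object
    gae_model: gae.GAEModel
    node_features: np.ndarray


def fit_pipeline(
    sims: _AttributeSimilarities,
    train_PMA: AssociationMatrix,
    train_pairs: Sequence[tuple[str, str]],
    train_labels: Sequence[int],
    config: RunConfig,
) -> FittedModel:
    """Fit features -> fusion -> SAE -> GAE -> classifier from training data only."""
    gip_pg = feat.gip_kernel(train_PMA, axis="rows")
    gip_mi = feat.gip_kernel(train_PMA, axis="cols")
    pg_filled = [feat.fill_zeros(S, gip_pg) for S in sims.pg_views]
    mi_filled = [feat.fill_zeros(S, gip_mi) for S in sims.mi_views]

    K = config.snf_neighbors
    fused_pg = fus.snf_fuse(pg_filled, K=min(K, len(sims.pg_ids) - 1),
                            t_max=config.snf_iterations)
    fused_mi = fus.snf_fuse(mi_filled, K=min(K, len(sims.mi_ids) - 1),
                            t_max=config.snf_iterations)

    PS1 = fus.sae_reduce(fus.sae_input_profile(fused_pg), out_dim=config.sae_dim,
                         seed=config.stage_seed("sae_pg"),
                         hidden=config.sae_hidden, epochs=config.sae_epochs)
    MS1 = fus.sae_reduce(fus.sae_input_profile(fused_mi), out_dim=config.sae_dim,
                         seed=config.stage_seed("sae_mi"),
                         hidden=config.sae_hidden, epochs=config.sae_epochs)
    X = fus.build_node_features(fus.dual_standardize(PS1), fus.dual_standardize(MS1))

    graph = gae.build_adjacency(train_PMA, X)
    model = gae.train_gae(graph, config)
    Z = {nid: model.Z[i] for i, nid in enumerate(graph.node_ids)}

    train_set = pred.build_pair_set(Z, train_pairs, train_labels)
    clf = pred.train_classifier(train_set, seed=config.stage_seed("xgb"), config=config)
    return FittedModel(embeddings=Z, classifier=clf, gae_model=model, node_features=X)


def _masked_matrix(
    pg_ids: Sequence[str],
    mi_ids: Sequence[str],
    positives: Sequence[tuple[str, str]],
) -> AssociationMatrix:
    ridx = {r: i for i, r in enumerate(pg_ids)}
    cidx = {c: j for j, c in enumerate(mi_ids)}
    m = np.zeros((len(pg_ids), len(mi_ids)))
    for r, c in positives:
        m[ridx[r], cidx[c]] = 1.0
    return AssociationMatrix(tuple(pg_ids), tuple(mi_ids), m)


# ---------------------------------------------------------------------------
# top-level protocols


def run_cv(dataset: Dataset, config: RunConfig) -> EvalReport:
    """Five-fold (configurable) cross-validation of the full pipeline.

    Negatives are sampled once per experiment at ``config.neg_ratio`` and
    split alongside the positives.  For every fold the feature path and the
    GAE adjacency are rebuilt from training positives only (unless
    ``config.mask_test_edges`` is off, which mimics embedding once on the
    full graph), the classifier is retrained, and test pairs are scored.
    """
    sims = attribute_similarities(dataset, config)
    full_PMA = feat.association_matrix(
        dataset.associations, row_order=sims.pg_ids, col_order=sims.mi_ids
    )
    positives = list(dataset.associations.pairs)
    negatives = sample_negatives(full_PMA, config.neg_ratio,
                                 seed=config.stage_seed("negatives"))
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    folds = kfold_split(pairs, labels, config.cv_folds,
                        seed=config.stage_seed("folds"))

    per_fold: list[dict[str, float]] = []
    for fold_idx, (tr, te) in enumerate(folds):
        train_pairs = [pairs[i] for i in tr]
        train_labels = labels[tr]
        test_pairs = [pairs[i] for i in te]
        test_labels = labels[te]
        if config.mask_test_edges:
            train_pos = [p for p, l in zip(train_pairs, train_labels) if l == 1]
        else:
            train_pos = positives
        train_PMA = _masked_matrix(sims.pg_ids, sims.mi_ids, train_pos)
        try:
            model = fit_pipeline(sims, train_PMA, train_pairs, train_labels, config)
        except Exception as exc:
            raise RuntimeError(f"fold {fold_idx}: {exc}") from exc
        test_set = pred.build_pair_set(model.embeddings, test_pairs, test_labels)
        scores = pred.predict_scores(model.classifier, test_set)
        entry = confusion_metrics(test_labels, scores, threshold=config.threshold)
        auc, aupr = auc_aupr(test_labels, scores)
        entry.update(auc=auc, aupr=aupr, fold=float(fold_idx))
        per_fold.append(entry)
    return EvalReport(per_fold=per_fold, config=config.to_dict(),
                      seed=config.random_seed)


def case_study(
    dataset: Dataset,
    holdout_pseudogenes: Sequence[str],
    top_k: int,
    config: RunConfig,
) -> dict[str, list[tuple[str, float]]]:
    """Leave-pseudogene-out ranking protocol.

    Every association involving a holdout pseudogene is dropped from training
    (and from the GAE adjacency); the model is trained once; all miRNAs are
    then ranked for each holdout pseudogene.
    """
    sims = attribute_similarities(dataset, config)
    missing = set(holdout_pseudogenes) - set(sims.pg_ids)
    if missing:
        raise ValueError(f"holdout pseudogene(s) not in dataset: {sorted(missing)}")
    holdout = set(holdout_pseudogenes)
    train_pos = [p for p in dataset.associations.pairs if p[0] not in holdout]
    train_PMA = _masked_matrix(sims.pg_ids, sims.mi_ids, train_pos)
    negatives = sample_negatives(train_PMA, config.neg_ratio,
                                 seed=config.stage_seed("negatives"))
    # negatives among holdout rows would leak the holdout identity into training
    negatives = [p for p in negatives if p[0] not in holdout]
    train_pairs = train_pos + negatives
    train_labels = np.array([1] * len(train_pos) + [0] * len(negatives))
    model = fit_pipeline(sims, train_PMA, train_pairs, train_labels, config)
    return {
        pg: pred.rank_candidates(model.classifier, model.embeddings, pg,
                                 list(sims.mi_ids), top_k=top_k)
        for pg in holdout_pseudogenes
    }
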