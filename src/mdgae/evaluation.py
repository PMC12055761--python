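"""Cross-validated link-prediction evaluation.

Observed edges are split into k folds; for each fold the held-out positives
are removed from the training adjacency, the full pipeline (NMF features,
then masked-autoencoder training) is re-run on the reduced network, and the
held-out positives plus an equal number of fixed never-observed negative
pairs are scored.  NMF features are recomputed per fold on the reduced
adjacency only, so held-out edges cannot leak into the features.

Eight metrics are reported per fold: AUC, AUPR (step-wise precision-recall
integration), and the threshold-0.5 confusion-matrix metrics ACC, SEN, PRE,
SPE, F1 and MCC.  Denominator-free cases (e.g. no predicted positives) are
reported as 0 with a warning flag rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nmf
from .gae import (
    DecoderConfig,
    EncoderConfig,
    TrainingConfig,
    TrainResult,
    derive_seed,
    sample_negative_pairs,
    train,
)
from .network import AssociationNetwork

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "UndefinedMetricError",
    "kfold_edge_split",
    "compute_metrics",
    "mean_report",
    "cross_validate",
]

METRIC_NAMES = ("auc", "aupr", "acc", "sen", "pre", "spe", "f1", "mcc")


class UndefinedMetricError(ValueError):
    """Raised when AUC/AUPR are requested with a single-class label vector."""


@dataclass(frozen=True)
class FoldSplit:
    """Per-fold held-out positive edges and fixed negative pairs."""

    k: int
    positives: tuple[tuple[tuple[int, int], ...], ...]
    negatives: tuple[tuple[tuple[int, int], ...], ...]


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation's eight metrics; ``warnings`` flags zero-denominator
    metrics that were reported as 0."""

    auc: float
    aupr: float
    acc: float
    sen: float
    pre: float
    spe: float
    f1: float
    mcc: float
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def kfold_edge_split(network: AssociationNetwork, k: int, seed: int) -> FoldSplit:
    """Shuffle observed edges into k folds and draw fixed per-fold negatives.

    Fold sizes differ by at most one.  Each fold's negatives are sampled 1:1
    with its positives from never-observed pairs, disjoint across folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    edges = network.edge_index_pairs()
    if len(edges) < k:
        raise ValueError(f"cannot split {len(edges)} edges into {k} folds")
    rng = np.random.default_rng(derive_seed(seed, "folds"))
    order = rng.permutation(len(edges))
    chunks = np.array_split(order, k)

    positives, negatives = [], []
    used_negatives: set[tuple[int, int]] = set()
    for fold, chunk in enumerate(chunks):
        fold_pos = tuple((int(i), int(j)) for i, j in edges[chunk])
        fold_neg = sample_negative_pairs(
            network,
            len(fold_pos),
            seed=derive_seed(seed, "negatives", k, fold),
            exclude=used_negatives,
        )
        used_negatives |= fold_neg
        positives.append(fold_pos)
        negatives.append(tuple(sorted(fold_neg)))
    return FoldSplit(k, tuple(positives), tuple(negatives))


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Eight-way evaluation of scored pairs against binary labels.

    AUC is the probability a random positive outscores a random negative
    (ties count one half); AUPR is the step-wise area under precision-recall.
    The remaining metrics come from the confusion matrix at ``threshold``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    labels = labels.astype(np.int64)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC/AUPR need both classes present")

    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))

    predicted = scores >= threshold
    tp = int(np.sum(predicted & (labels == 1)))
    fp = int(np.sum(predicted & (labels == 0)))
    fn = int(np.sum(~predicted & (labels == 1)))
    tn = int(np.sum(~predicted & (labels == 0)))

    warnings: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / (tp + fp + fn + tn)
    sen = ratio(tp, tp + fn, "sen")
    pre = ratio(tp, tp + fp, "pre")
    spe = ratio(tn, tn + fp, "spe")
    f1 = ratio(2 * pre * sen, pre + sen, "f1")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    return MetricsReport(auc, aupr, acc, sen, pre, spe, f1, mcc, tuple(warnings))


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each metric across reports."""
    values = {
        name: float(np.mean([getattr(r, name) for r in reports]))
        for name in METRIC_NAMES
    }
    flagged = tuple(sorted({w for r in reports for w in r.warnings}))
    return MetricsReport(**values, warnings=flagged)


def _remove_edges(
    network: AssociationNetwork, edges: tuple[tuple[int, int], ...]
) -> AssociationNetwork:
    adjacency = network.adjacency.copy()
    for i, j in edges:
        adjacency[i, j] = 0
    return network.with_adjacency(adjacency)


def cross_validate(
    network: AssociationNetwork,
    nmf_config: nmf.NMFConfig,
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    training_config: TrainingConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation of the full pipeline on one network.

    Returns the per-fold reports and their arithmetic mean.
    """
    split = kfold_edge_split(network, k, seed)
    training_config = training_config or TrainingConfig()
    reports: list[MetricsReport] = []
    for fold in range(k):
        held_pos = split.positives[fold]
        held_neg = split.negatives[fold]
        reduced = _remove_edges(network, held_pos)

        fold_nmf = nmf.NMFConfig(
            **{**nmf_config.__dict__, "seed": derive_seed(seed, "nmf", fold)}
        )
        factors, _ = nmf.factorize(reduced, fold_nmf)
        features = nmf.node_features(factors)

        fold_training = training_config.model_copy(
            update={"seed": derive_seed(training_config.seed, "params", fold)}
        )
        try:
            result: TrainResult = train(
                reduced, features, encoder_config, decoder_config, fold_training
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}") from exc

        pairs = list(held_pos) + list(held_neg)
        scores = result.model.score_pairs(result.embeddings, pairs)
        labels = np.concatenate([np.ones(len(held_pos)), np.zeros(len(held_neg))])
        reports.append(compute_metrics(scores, labels))
    return reports, mean_report(reports)
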