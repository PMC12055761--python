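"""Whole-matrix scoring and hold-out case-study protocols.

After training, every metabolite-disease pair receives a score in [0, 1];
ranked slices of the score table drive two discovery protocols:

* leave-disease-out — remove every edge of one disease, retrain the full
  pipeline (NMF features, then the masked autoencoder) on the reduced
  network, and rank that disease's candidate metabolites;
* leave-metabolite-out — the symmetric protocol ranking diseases for one
  held-out metabolite.

Ties are broken lexicographically by identifier so ranked output is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nmf
from .gae import (
    DecoderConfig,
    EncoderConfig,
    GAEModel,
    NodeEmbeddings,
    TrainingConfig,
    train,
)
from .network import AssociationNetwork

__all__ = [
    "ScoreTable",
    "score_all_pairs",
    "rank_metabolites_for_disease",
    "rank_diseases_for_metabolite",
    "leave_disease_out",
    "leave_metabolite_out",
]


@dataclass(frozen=True)
class ScoreTable:
    """U x V matrix of association scores aligned to a network's identifiers."""

    metabolite_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if scores.shape != (len(self.metabolite_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape must match the identifier lists")
        if scores.min() < 0 or scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)


def score_all_pairs(
    embeddings: NodeEmbeddings,
    parameters: GAEModel,
    decoder_config: DecoderConfig,
    network: AssociationNetwork,
) -> ScoreTable:
    """Score every metabolite-disease pair with the trained edge decoder."""
    if parameters.decoder_config != decoder_config:
        raise ValueError("parameters were built for a different decoder config")
    U, V = embeddings.H_m.shape[0], embeddings.H_d.shape[0]
    if (U, V) != (network.n_metabolites, network.n_diseases):
        raise ValueError("embeddings do not match the network dimensions")
    grid = np.stack(
        [np.repeat(np.arange(U), V), np.tile(np.arange(V), U)], axis=1
    )
    scores = parameters.score_pairs(embeddings, grid).reshape(U, V)
    return ScoreTable(network.metabolite_ids, network.disease_ids, scores)


def _ranked(ids, scores, top_k: int, exclude: set[int]) -> list[tuple[str, float]]:
    entries = [
        (ids[i], float(scores[i])) for i in range(len(ids)) if i not in exclude
    ]
    entries.sort(key=lambda item: (-item[1], item[0]))
    return entries[:top_k]


def rank_metabolites_for_disease(
    table: ScoreTable,
    disease_id: str,
    top_k: int = 20,
    exclude_known: bool = True,
    network: AssociationNetwork | None = None,
) -> list[tuple[str, float]]:
    """Top metabolite candidates for one disease, descending by score.

    With ``exclude_known=True``, metabolites already associated with the
    disease in ``network`` are removed (discovery mode); the hold-out
    protocols keep them rankable with ``exclude_known=False``.
    """
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    try:
        col = table.disease_ids.index(disease_id)
    except ValueError:
        raise KeyError(f"unknown disease identifier: {disease_id!r}") from None
    exclude: set[int] = set()
    if exclude_known:
        if network is None:
            raise ValueError("exclude_known=True requires the network")
        exclude = set(np.flatnonzero(network.adjacency[:, col] == 1).tolist())
    return _ranked(table.metabolite_ids, table.scores[:, col], top_k, exclude)


def rank_diseases_for_metabolite(
    table: ScoreTable,
    metabolite_id: str,
    top_k: int = 20,
    exclude_known: bool = True,
    network: AssociationNetwork | None = None,
) -> list[tuple[str, float]]:
    """Top disease candidates for one metabolite; mirror of the disease case."""
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    try:
        row = table.metabolite_ids.index(metabolite_id)
    except ValueError:
        raise KeyError(f"unknown metabolite identifier: {metabolite_id!r}") from None
    exclude: set[int] = set()
    if exclude_known:
        if network is None:
            raise ValueError("exclude_known=True requires the network")
        exclude = set(np.flatnonzero(network.adjacency[row, :] == 1).tolist())
    return _ranked(table.disease_ids, table.scores[row, :], top_k, exclude)


def _holdout_pipeline(
    reduced: AssociationNetwork,
    nmf_config: nmf.NMFConfig,
    encoder_config: EncoderConfig | None,
    decoder_config: DecoderConfig | None,
    training_config: TrainingConfig | None,
) -> ScoreTable:
    factors, _ = nmf.factorize(reduced, nmf_config)
    features = nmf.node_features(factors)
    result = train(reduced, features, encoder_config, decoder_config, training_config)
    return score_all_pairs(
        result.embeddings,
        result.model,
        result.model.decoder_config,
        reduced,
    )


def leave_disease_out(
    network: AssociationNetwork,
    disease_id: str,
    nmf_config: nmf.NMFConfig,
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    training_config: TrainingConfig | None = None,
    top_k: int = 20,
) -> list[tuple[str, float]]:
    """Rank a disease's metabolites after hiding all its edges from training.

    Every edge incident to ``disease_id`` is removed before the NMF and
    autoencoder stages see the network, then the disease's full metabolite
    column is ranked (known positives stay rankable).
    """
    col = network.disease_index(disease_id)
    if network.adjacency[:, col].sum() == 0:
        raise ValueError(f"disease {disease_id!r} has no observed associations")
    adjacency = network.adjacency.copy()
    adjacency[:, col] = 0
    reduced = network.with_adjacency(adjacency)
    assert reduced.adjacency[:, col].sum() == 0  # exclusion contract
    table = _holdout_pipeline(
        reduced, nmf_config, encoder_config, decoder_config, training_config
    )
    return rank_metabolites_for_disease(
        table, disease_id, top_k=top_k, exclude_known=False
    )


def leave_metabolite_out(
    network: AssociationNetwork,
    metabolite_id: str,
    nmf_config: nmf.NMFConfig,
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    training_config: TrainingConfig | None = None,
    top_k: int = 20,
) -> list[tuple[str, float]]:
    """Rank a metabolite's diseases after hiding all its edges from training."""
    row = network.metabolite_index(metabolite_id)
    if network.adjacency[row, :].sum() == 0:
        raise ValueError(f"metabolite {metabolite_id!r} has no observed associations")
    adjacency = network.adjacency.copy()
    adjacency[row, :] = 0
    reduced = network.with_adjacency(adjacency)
    assert reduced.adjacency[row, :].sum() == 0  # exclusion contract
    table = _holdout_pipeline(
        reduced, nmf_config, encoder_config, decoder_config, training_config
    )
    return rank_diseases_for_metabolite(
        table, metabolite_id, top_k=top_k, exclude_known=False
    )
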