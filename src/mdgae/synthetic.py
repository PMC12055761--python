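"""Planted low-rank bipartite network generator.

Every downstream stage (NMF features, masked autoencoder, cross-validation,
hold-out ranking) is exercised on synthetic networks whose ground truth is
known.  The generative model mirrors the structural assumption the feature
extractor makes: the association score matrix is a product of two entrywise
non-negative factors, so the clean network is exactly low-rank before
thresholding.

Generation is quantile-thresholded — the ``floor(U * V * density)`` largest
scores become edges — so the edge count is controlled exactly and fixtures
are deterministic.  Optional flip noise toggles a uniformly chosen fraction
of *all* entries, deleting true edges and adding spurious ones, which is how
misclassified association / non-association pairs enter curated datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AssociationNetwork

__all__ = ["PlantedConfig", "generate_planted_network", "flip_entries"]


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted low-rank model.

    Attributes
    ----------
    U, V
        Numbers of metabolites and diseases.
    true_rank
        Rank of the planted score matrix; must be < min(U, V).
    density
        Fraction of the U*V pairs turned into edges (before noise).
    noise_flip_rate
        Fraction of all U*V entries toggled after thresholding, in [0, 1).
    seed
        Seed for factor sampling and noise placement.
    """

    U: int
    V: int
    true_rank: int
    density: float
    noise_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.U <= 0 or self.V <= 0:
            raise ValueError("U and V must be positive")
        if not 0 < self.true_rank < min(self.U, self.V):
            raise ValueError("true_rank must satisfy 0 < true_rank < min(U, V)")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if int(self.U * self.V * self.density) < 1:
            raise ValueError("density yields zero edges")
        if not 0.0 <= self.noise_flip_rate < 1.0:
            raise ValueError("noise_flip_rate must lie in [0, 1)")


def _identifiers(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def generate_planted_network(
    config: PlantedConfig,
) -> tuple[AssociationNetwork, tuple[np.ndarray, np.ndarray]]:
    """Sample a planted network and its ground-truth factors.

    Factor entries are i.i.d. uniform on [0, 1); the score matrix is their
    product; the ``floor(U * V * density)`` top-scoring pairs become edges
    (ties broken by flat index order); finally ``round(rho * U * V)`` entries
    are flipped when ``noise_flip_rate = rho > 0``.

    Returns
    -------
    (network, (M_true, D_true))
        The network plus the planted factors of shapes (U, rank), (rank, V).
    """
    rng = np.random.default_rng(config.seed)
    m_true = rng.random((config.U, config.true_rank))
    d_true = rng.random((config.true_rank, config.V))
    scores = m_true @ d_true

    n_edges = int(config.U * config.V * config.density)
    flat = scores.ravel()
    # stable sort on (-score, index): ties resolve to the lower flat index
    order = np.argsort(-flat, kind="stable")
    adjacency = np.zeros(config.U * config.V, dtype=np.int8)
    adjacency[order[:n_edges]] = 1
    adjacency = adjacency.reshape(config.U, config.V)

    network = AssociationNetwork(
        _identifiers("M", config.U), _identifiers("D", config.V), adjacency
    )
    if config.noise_flip_rate > 0:
        # independent stream so the flip set does not perturb factor sampling
        network = flip_entries(
            network, config.noise_flip_rate, seed=int(rng.integers(2**31))
        )
    return network, (m_true, d_true)


def flip_entries(
    network: AssociationNetwork, rho: float, seed: int
) -> AssociationNetwork:
    """Toggle ``round(rho * U * V)`` uniformly chosen adjacency entries.

    Flipping is an involution: applying the same ``(rho, seed)`` twice
    restores the original network.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("flip rate must lie in [0, 1)")
    n_cells = network.n_metabolites * network.n_diseases
    n_flips = round(rho * n_cells)
    if n_flips == 0:
        return network
    rng = np.random.default_rng(seed)
    positions = rng.choice(n_cells, size=n_flips, replace=False)
    adjacency = network.adjacency.copy().ravel()
    adjacency[positions] ^= 1
    return network.with_adjacency(adjacency.reshape(network.adjacency.shape))
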