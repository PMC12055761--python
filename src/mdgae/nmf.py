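"""Regularized non-negative matrix factorization of the association matrix.

The binary adjacency ``A`` (U metabolites x V diseases) is approximated by a
product of non-negative factors, ``A ~ M @ D`` with ``M`` of shape (U, K) and
``D`` of shape (K, V).  The objective is a weighted Frobenius data term with
Tikhonov (squared Frobenius) penalties on both factors::

    || W . (A - M D) ||_F^2  +  mu1 ||M||_F^2  +  mu2 ||D||_F^2

where ``.`` is the Hadamard product and ``W`` is a binary weight matrix
(all-ones by default, or the observed-entry indicator so that only known
associations constrain the fit).  Minimization uses the classic multiplicative
update rules, which preserve non-negativity::

    M <- M . (W.A) D^T      / ((W.(M D)) D^T      + mu1 M)
    D <- D . M^T (W.A)      / (M^T (W.(M D))      + mu2 D)

applied alternately, the D-update seeing the freshly updated M.  A small
guard ``eps_div`` is added to denominators so entries that reach zero stay
zero instead of producing NaNs.  Rows of ``M`` are the initial metabolite
features and columns of ``D`` the initial disease features handed to the
graph autoencoder.

The latent dimension must satisfy ``K < min(U, V)`` and ``K < U*V/(U+V)``,
i.e. the factorization must compress the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import AssociationNetwork

__all__ = [
    "NMFConfig",
    "FactorPair",
    "validate_latent_dim",
    "weight_matrix",
    "initialize_factors",
    "nmf_objective",
    "update_step",
    "factorize",
    "node_features",
]


@dataclass(frozen=True)
class NMFConfig:
    """Hyperparameters of the regularized factorization.

    ``K=90`` and ``mu1 = mu2 = 0.01`` are the defaults used on the curated
    association dataset; smaller networks need a smaller ``K`` to satisfy the
    compression constraint (see :func:`validate_latent_dim`).
    """

    K: int = 90
    mu1: float = 0.01
    mu2: float = 0.01
    max_iterations: int = 500
    rel_tolerance: float = 1e-6
    eps_div: float = 1e-12
    seed: int = 0
    weight_mode: str = "ones"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rel_tolerance < 0:
            raise ValueError("rel_tolerance must be non-negative")
        if self.eps_div <= 0:
            raise ValueError("eps_div must be positive")
        if self.weight_mode not in ("ones", "observed"):
            raise ValueError(f"unknown weight_mode: {self.weight_mode!r}")


@dataclass(frozen=True)
class FactorPair:
    """Non-negative factors ``M`` (U x K) and ``D`` (K x V)."""

    M: np.ndarray = field(repr=False)
    D: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.float64)
        D = np.asarray(self.D, dtype=np.float64)
        if M.ndim != 2 or D.ndim != 2 or M.shape[1] != D.shape[0]:
            raise ValueError(f"inconsistent factor shapes {M.shape}, {D.shape}")
        if (M < 0).any() or (D < 0).any():
            raise ValueError("factors must be entrywise non-negative")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "D", D)

    @property
    def K(self) -> int:
        return self.M.shape[1]

    def product(self) -> np.ndarray:
        return self.M @ self.D


def validate_latent_dim(U: int, V: int, K: int) -> None:
    """Enforce K < min(U, V) and K < U*V / (U + V)."""
    if K >= min(U, V):
        raise ValueError(f"K={K} must be smaller than both U={U} and V={V}")
    if K >= U * V / (U + V):
        raise ValueError(f"K={K} must be smaller than U*V/(U+V) = {U * V / (U + V):.3f}")


def weight_matrix(network: AssociationNetwork, mode: str) -> np.ndarray:
    """Binary weight matrix: all-ones, or the observed-entry indicator."""
    if mode == "ones":
        return np.ones(network.adjacency.shape)
    if mode == "observed":
        return network.adjacency.astype(np.float64)
    raise ValueError(f"unknown weight_mode: {mode!r}")


def initialize_factors(U: int, V: int, K: int, seed: int) -> FactorPair:
    """Seeded strictly positive uniform initialization.

    Entries are uniform on (0, 1]; strict positivity matters because the
    multiplicative updates lock zero entries at zero forever.
    """
    validate_latent_dim(U, V, K)
    rng = np.random.default_rng(seed)
    # 1 - U[0,1) lies in (0, 1]
    return FactorPair(1.0 - rng.random((U, K)), 1.0 - rng.random((K, V)))


def nmf_objective(
    A: np.ndarray,
    W: np.ndarray,
    factors: FactorPair,
    mu1: float,
    mu2: float,
) -> float:
    """Weighted residual plus Tikhonov penalties; always >= 0."""
    A = np.asarray(A, dtype=np.float64)
    if A.shape != W.shape or A.shape != (factors.M.shape[0], factors.D.shape[1]):
        raise ValueError("adjacency, weight and factor shapes do not conform")
    residual = W * (A - factors.product())
    return float(
        (residual**2).sum() + mu1 * (factors.M**2).sum() + mu2 * (factors.D**2).sum()
    )


def update_step(
    A: np.ndarray,
    W: np.ndarray,
    factors: FactorPair,
    mu1: float,
    mu2: float,
    eps_div: float = 1e-12,
) -> FactorPair:
    """One alternating multiplicative update: M first, then D with the new M."""
    A = np.asarray(A, dtype=np.float64)
    M, D = factors.M, factors.D
    WA = W * A

    numer_m = WA @ D.T
    denom_m = (W * (M @ D)) @ D.T + mu1 * M + eps_div
    M = M * (numer_m / denom_m)

    numer_d = M.T @ WA
    denom_d = M.T @ (W * (M @ D)) + mu2 * D + eps_div
    D = D * (numer_d / denom_d)
    return FactorPair(M, D)


def factorize(
    network: AssociationNetwork, config: NMFConfig
) -> tuple[FactorPair, list[float]]:
    """Run multiplicative updates to (local) convergence.

    Iterates :func:`update_step` until ``max_iterations`` or until the
    relative objective decrease falls below ``rel_tolerance``.  Returns the
    final factors and the objective trace (objective before any update,
    then after each update), useful as a convergence diagnostic.
    """
    U, V = network.n_metabolites, network.n_diseases
    validate_latent_dim(U, V, config.K)
    A = network.adjacency.astype(np.float64)
    W = weight_matrix(network, config.weight_mode)
    factors = initialize_factors(U, V, config.K, config.seed)

    trace = [nmf_objective(A, W, factors, config.mu1, config.mu2)]
    for _ in range(config.max_iterations):
        factors = update_step(A, W, factors, config.mu1, config.mu2, config.eps_div)
        trace.append(nmf_objective(A, W, factors, config.mu1, config.mu2))
        prev, cur = trace[-2], trace[-1]
        if prev == 0 or abs(prev - cur) / max(prev, 1e-300) < config.rel_tolerance:
            break
    return factors, trace


def node_features(factors: FactorPair) -> tuple[np.ndarray, np.ndarray]:
    """Initial node features: rows of M (U x K) and columns of D as (V x K)."""
    return factors.M.copy(), factors.D.T.copy()
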