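"""Masked graph autoencoder for bipartite association networks.

The model reconstructs the metabolite-disease network from noisy
observations.  Each training epoch

1. draws a fresh Bernoulli(tau) mask over the observed edges; masked edges
   are hidden from message passing but remain positive supervision targets,
2. encodes both node partitions with a graph neural network (GIN by
   default; GCN and GAT variants available) run on the *reserved* edges only,
3. decodes with two heads: an edge decoder scoring metabolite-disease pairs
   in [0, 1] via an MLP over a pair combiner (Hadamard product by default),
   and a degree decoder regressing each node's observed association count,
4. takes one full-graph Adam step on ``L = L_edge + l * L_degree`` where
   ``L_edge`` is binary cross-entropy over all observed edges plus an equal
   number of resampled negative pairs, and ``L_degree`` is mean squared error
   against the degrees of the full observed graph.

The masking is the noise-robustness mechanism: an encoder that never sees a
fixed edge set cannot overfit spurious associations, while the degree decoder
anchors each node's neighborhood density.

The GIN update for metabolite ``a`` at layer ``t`` is

    H_a^t = MLP^t( (1 + eps^t) * H_a^{t-1} + sum_{b in N(a)} H_b^{t-1} )

with the symmetric rule for diseases; ``eps^t`` is a trainable scalar blend
parameter.  Both partitions share the layer MLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .autodiff import Adam, Tensor, glorot_uniform
from .network import AssociationNetwork, node_degrees

__all__ = [
    "MaskSplit",
    "EncoderConfig",
    "DecoderConfig",
    "TrainingConfig",
    "NodeEmbeddings",
    "GAEModel",
    "TrainResult",
    "TrainingDivergenceError",
    "SamplingError",
    "derive_seed",
    "mask_edges",
    "encode",
    "edge_score",
    "bce_edge_loss",
    "degree_predict",
    "degree_loss",
    "total_loss",
    "sample_negative_pairs",
    "train",
]

BCE_CLIP = 1e-7

# documented stage codes for per-stage seed derivation from one global seed
_STAGE_CODES = {"nmf": 0, "mask": 1, "negatives": 2, "params": 3, "features": 4, "folds": 5}


def derive_seed(base_seed: int, stage: str, *indices: int) -> int:
    """Derive an independent sub-seed for a named pipeline stage.

    Stages: nmf, mask, negatives, params, features, folds.  Extra indices
    (epoch, fold) extend the entropy chain.  Result is < 2**31.
    """
    seq = np.random.SeedSequence([int(base_seed), _STAGE_CODES[stage], *map(int, indices)])
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


class TrainingDivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


class SamplingError(ValueError):
    """Raised when a negative-pair sample cannot be drawn."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


class EncoderConfig(BaseModel):
    """Graph encoder settings; GIN with dims [64, 128] by default."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    variant: Literal["GIN", "GCN", "GAT"] = "GIN"
    layer_dims: tuple[int, ...] = (64, 128)
    eps_init: float = 0.0

    @model_validator(mode="after")
    def _check_dims(self):
        if not 2 <= len(self.layer_dims) <= 4:
            raise ValueError("number of encoder layers must be between 2 and 4")
        if any(d < 1 for d in self.layer_dims):
            raise ValueError("layer dimensions must be positive")
        return self

    @property
    def num_layers(self) -> int:
        return len(self.layer_dims)


class DecoderConfig(BaseModel):
    """Edge- and degree-decoder settings; hidden dims [128, 64] by default."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    combiner: Literal["hadamard", "concat", "sum", "inner"] = "hadamard"
    hidden_dims: tuple[int, ...] = (128, 64)
    degree_decoder_hidden: tuple[int, ...] = (128, 64)


class TrainingConfig(BaseModel):
    """Optimization settings and ablation switches.

    ``use_masking=False`` forces tau to 0 (the "w/o m" ablation),
    ``use_degree_decoder=False`` forces the loss weight to 0 ("w/o d"), and
    ``use_nmf_features=False`` swaps the initial features for seeded uniform
    noise of the same shape ("w/o n").
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    epochs: int = Field(default=300, ge=1)
    learning_rate: float = Field(default=0.001, gt=0)
    tau: float = Field(default=0.4, ge=0.0, le=1.0)
    loss_weight: float = Field(default=0.6, ge=0.0)
    negative_ratio: float = Field(default=1.0, gt=0.0)
    seed: int = 0
    use_degree_decoder: bool = True
    use_masking: bool = True
    use_nmf_features: bool = True


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskSplit:
    """Partition of the observed edges into masked and reserved sets."""

    masked_edges: frozenset[tuple[int, int]]
    reserved_edges: frozenset[tuple[int, int]]
    tau: float

    def __post_init__(self) -> None:
        if self.masked_edges & self.reserved_edges:
            raise ValueError("masked and reserved edge sets must be disjoint")


def mask_edges(network: AssociationNetwork, tau: float, seed: int) -> MaskSplit:
    """Assign each observed edge to the mask independently with rate ``tau``."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("masking rate must lie in [0, 1]")
    edges = network.edge_index_pairs()
    rng = np.random.default_rng(seed)
    masked = rng.random(len(edges)) < tau
    to_pairs = lambda rows: frozenset((int(i), int(j)) for i, j in rows)
    return MaskSplit(to_pairs(edges[masked]), to_pairs(edges[~masked]), tau)


def _reserved_adjacency(network: AssociationNetwork, split: MaskSplit | None) -> np.ndarray:
    adj = network.adjacency.astype(np.float64)
    if split is None:
        return adj
    reserved = np.zeros_like(adj)
    if split.reserved_edges:
        rows, cols = zip(*split.reserved_edges)
        reserved[list(rows), list(cols)] = 1.0
    if not np.all(adj[reserved == 1] == 1):
        raise ValueError("reserved edges must be observed edges")
    return reserved


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeEmbeddings:
    """Final latent node vectors for both partitions."""

    H_m: np.ndarray = field(repr=False)
    H_d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        H_m = np.asarray(self.H_m, dtype=np.float64)
        H_d = np.asarray(self.H_d, dtype=np.float64)
        if H_m.ndim != 2 or H_d.ndim != 2 or H_m.shape[1] != H_d.shape[1]:
            raise ValueError("embedding matrices must share their latent dimension")
        if not (np.isfinite(H_m).all() and np.isfinite(H_d).all()):
            raise ValueError("embeddings must be finite")
        object.__setattr__(self, "H_m", H_m)
        object.__setattr__(self, "H_d", H_d)

    @property
    def dim(self) -> int:
        return self.H_m.shape[1]


def _mlp_params(rng, dims: Sequence[int]) -> list[tuple[Tensor, Tensor]]:
    layers = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        W = Tensor(glorot_uniform(rng, fan_in, fan_out), requires_grad=True)
        b = Tensor(np.zeros(fan_out), requires_grad=True)
        layers.append((W, b))
    return layers


def _mlp_forward(
    x: Tensor, layers: list[tuple[Tensor, Tensor]], final_activation: str
) -> Tensor:
    for k, (W, b) in enumerate(layers):
        x = x @ W + b
        if k < len(layers) - 1:
            x = x.relu()
    if final_activation == "relu":
        x = x.relu()
    elif final_activation == "sigmoid":
        x = x.sigmoid()
    return x


class GAEModel:
    """Parameter container and forward passes for encoder and decoders.

    All parameters are Glorot-initialized from a single seed, so a model is
    bit-reproducible from ``(configs, feature_dim, seed)``.
    """

    def __init__(
        self,
        encoder_config: EncoderConfig,
        decoder_config: DecoderConfig,
        feature_dim: int,
        seed: int,
    ):
        self.encoder_config = encoder_config
        self.decoder_config = decoder_config
        self.feature_dim = feature_dim
        rng = np.random.default_rng(seed)

        dims = [feature_dim, *encoder_config.layer_dims]
        self.encoder_layers: list[dict] = []
        for t in range(encoder_config.num_layers):
            d_in, d_out = dims[t], dims[t + 1]
            layer: dict = {}
            if encoder_config.variant == "GIN":
                layer["mlp"] = _mlp_params(rng, [d_in, d_out, d_out])
                layer["eps"] = Tensor(float(encoder_config.eps_init), requires_grad=True)
            elif encoder_config.variant == "GCN":
                layer["W"] = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
                layer["b"] = Tensor(np.zeros(d_out), requires_grad=True)
            else:  # GAT, single head
                layer["W"] = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
                layer["a_src"] = Tensor(
                    glorot_uniform(rng, d_out, 1), requires_grad=True
                )
                layer["a_dst"] = Tensor(
                    glorot_uniform(rng, d_out, 1), requires_grad=True
                )
                layer["b"] = Tensor(np.zeros(d_out), requires_grad=True)
            self.encoder_layers.append(layer)

        d_emb = dims[-1]
        if decoder_config.combiner == "inner":
            self.edge_layers = None
            self.inner_scale = Tensor(1.0, requires_grad=True)
            self.inner_bias = Tensor(0.0, requires_grad=True)
        else:
            d_pair = 2 * d_emb if decoder_config.combiner == "concat" else d_emb
            self.edge_layers = _mlp_params(
                rng, [d_pair, *decoder_config.hidden_dims, 1]
            )
        self.degree_layers = _mlp_params(
            rng, [d_emb, *decoder_config.degree_decoder_hidden, 1]
        )

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.encoder_layers:
            for value in layer.values():
                if isinstance(value, Tensor):
                    params.append(value)
                else:
                    for W, b in value:
                        params.extend((W, b))
        if self.edge_layers is None:
            params.extend((self.inner_scale, self.inner_bias))
        else:
            for W, b in self.edge_layers:
                params.extend((W, b))
        for W, b in self.degree_layers:
            params.extend((W, b))
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.value = a.astype(np.float64).copy()

    # -- encoder ----------------------------------------------------------

    def encode_tensor(self, X: Tensor, biadjacency: np.ndarray) -> Tensor:
        """Run the encoder on stacked features X ((U+V) x K).

        ``biadjacency`` is the U x V reserved-edge matrix; message passing
        happens only along these edges.
        """
        U, V = biadjacency.shape
        n = U + V
        A_full = np.zeros((n, n))
        A_full[:U, U:] = biadjacency
        A_full[U:, :U] = biadjacency.T

        H = X
        variant = self.encoder_config.variant
        if variant == "GIN":
            A = Tensor(A_full)
            for layer in self.encoder_layers:
                agg = (1.0 + layer["eps"]) * H + A @ H
                H = _mlp_forward(agg, layer["mlp"], final_activation="none")
        elif variant == "GCN":
            A_hat = A_full + np.eye(n)
            d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
            A_norm = Tensor(A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :])
            for layer in self.encoder_layers:
                H = (A_norm @ H @ layer["W"] + layer["b"]).relu()
        else:  # GAT
            mask = (A_full + np.eye(n)) > 0
            neg_fill = Tensor(np.where(mask, 0.0, -1e30))
            mask_t = Tensor(mask.astype(np.float64))
            for layer in self.encoder_layers:
                Z = H @ layer["W"]
                e = (Z @ layer["a_src"]) + (Z @ layer["a_dst"]).T
                e = e.leaky_relu(0.2) + neg_fill
                # max-shifted masked softmax over each node's neighborhood
                shift = Tensor(e.value.max(axis=1, keepdims=True))
                w = (e - shift).exp() * mask_t
                alpha = w / w.sum(axis=1, keepdims=True)
                H = (alpha @ Z + layer["b"]).relu()
        return H

    # -- decoders ---------------------------------------------------------

    def edge_scores_tensor(self, H: Tensor, U: int, m_idx, d_idx) -> Tensor:
        """Scores in [0, 1] for pairs (m_idx[k], d_idx[k])."""
        hm = H.gather_rows(np.asarray(m_idx, dtype=np.intp))
        hd = H.gather_rows(np.asarray(d_idx, dtype=np.intp) + U)
        combiner = self.decoder_config.combiner
        if combiner == "inner":
            z = (hm * hd).sum(axis=1)
            return (z * self.inner_scale + self.inner_bias).sigmoid()
        if combiner == "hadamard":
            x = hm * hd
        elif combiner == "sum":
            x = hm + hd
        else:  # concat
            x = Tensor.concat([hm, hd], axis=1)
        out = _mlp_forward(x, self.edge_layers, final_activation="sigmoid")
        return out.reshape(-1)

    def degree_tensor(self, H: Tensor) -> Tensor:
        """Predicted degree for every node (metabolites then diseases)."""
        return _mlp_forward(H, self.degree_layers, final_activation="none").reshape(-1)

    # -- numpy-facing inference -------------------------------------------

    def embeddings(
        self,
        network: AssociationNetwork,
        features_m: np.ndarray,
        features_d: np.ndarray,
        split: MaskSplit | None = None,
    ) -> NodeEmbeddings:
        X = Tensor(np.vstack([features_m, features_d]))
        H = self.encode_tensor(X, _reserved_adjacency(network, split))
        U = network.n_metabolites
        return NodeEmbeddings(H.value[:U], H.value[U:])

    def score_pairs(self, embeddings: NodeEmbeddings, pairs) -> np.ndarray:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.intp))
        H = Tensor(np.vstack([embeddings.H_m, embeddings.H_d]))
        U = embeddings.H_m.shape[0]
        return self.edge_scores_tensor(H, U, pairs[:, 0], pairs[:, 1]).value


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def encode(
    network: AssociationNetwork,
    reserved: MaskSplit,
    features: tuple[np.ndarray, np.ndarray],
    config: EncoderConfig,
    parameters: GAEModel,
) -> NodeEmbeddings:
    """Encode node features using only the reserved edges of ``reserved``."""
    features_m, features_d = features
    if features_m.shape[0] != network.n_metabolites or features_d.shape[0] != network.n_diseases:
        raise ValueError("feature row counts must match the network partitions")
    if parameters.encoder_config != config:
        raise ValueError("parameters were built for a different encoder config")
    return parameters.embeddings(network, features_m, features_d, reserved)


def edge_score(
    pair: tuple[int, int],
    embeddings: NodeEmbeddings,
    config: DecoderConfig,
    parameters: GAEModel,
) -> float:
    """Association score in [0, 1] for one (metabolite, disease) index pair."""
    i, j = pair
    if not (0 <= i < embeddings.H_m.shape[0] and 0 <= j < embeddings.H_d.shape[0]):
        raise IndexError(f"pair {pair} out of range")
    if parameters.decoder_config != config:
        raise ValueError("parameters were built for a different decoder config")
    return float(parameters.score_pairs(embeddings, [(i, j)])[0])


def _bce_tensor(scores: Tensor, labels: np.ndarray) -> Tensor:
    s = scores.clip(BCE_CLIP, 1.0 - BCE_CLIP)
    y = Tensor(labels)
    return -(y * s.log() + (1.0 - y) * (1.0 - s).log()).mean()


def bce_edge_loss(scores, labels) -> float:
    """Mean binary cross-entropy with scores clipped to [1e-7, 1 - 1e-7]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return float(_bce_tensor(Tensor(scores), labels).value)


def degree_predict(embeddings: NodeEmbeddings, parameters: GAEModel) -> np.ndarray:
    """Predicted degrees, metabolites first then diseases (length U + V)."""
    H = Tensor(np.vstack([embeddings.H_m, embeddings.H_d]))
    return parameters.degree_tensor(H).value


def degree_loss(predicted, true_degrees) -> float:
    """Mean squared error between predicted and observed degrees."""
    predicted = np.asarray(predicted, dtype=np.float64)
    true_degrees = np.asarray(true_degrees, dtype=np.float64)
    if predicted.shape != true_degrees.shape:
        raise ValueError("degree vectors must have equal length")
    return float(np.mean((true_degrees - predicted) ** 2))


def total_loss(l_edge: float, l_degree: float, l: float) -> float:
    """Linear combination ``L_edge + l * L_degree``."""
    if l < 0:
        raise ValueError("loss weight must be non-negative")
    return l_edge + l * l_degree


def sample_negative_pairs(
    network: AssociationNetwork,
    n: int,
    seed: int,
    exclude: set[tuple[int, int]] | frozenset[tuple[int, int]] = frozenset(),
) -> set[tuple[int, int]]:
    """Uniform sample of ``n`` non-associated pairs, avoiding ``exclude``."""
    V = network.n_diseases
    zero_flat = np.flatnonzero(network.adjacency.ravel() == 0)
    if exclude:
        excluded_flat = np.fromiter(
            (i * V + j for i, j in exclude), dtype=np.int64, count=len(exclude)
        )
        zero_flat = np.setdiff1d(zero_flat, excluded_flat, assume_unique=False)
    if n > len(zero_flat):
        raise SamplingError(
            f"requested {n} negative pairs but only {len(zero_flat)} are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_flat, size=n, replace=False)
    return {(int(f) // V, int(f) % V) for f in chosen}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainResult:
    """Trained model, final embeddings and the per-epoch loss trace."""

    model: GAEModel
    embeddings: NodeEmbeddings
    loss_trace: tuple[dict, ...]


def train(
    network: AssociationNetwork,
    initial_features: tuple[np.ndarray, np.ndarray],
    encoder_config: EncoderConfig | None = None,
    decoder_config: DecoderConfig | None = None,
    training_config: TrainingConfig | None = None,
) -> TrainResult:
    """Train the masked autoencoder on one association network.

    Per epoch: fresh Bernoulli mask, encode on reserved edges, score all
    observed edges (masked included) plus freshly resampled 1:1 negatives,
    regress degrees of the full observed graph, one Adam step on the combined
    loss.  Final embeddings are computed on the complete observed graph.
    """
    encoder_config = encoder_config or EncoderConfig()
    decoder_config = decoder_config or DecoderConfig()
    cfg = training_config or TrainingConfig()

    features_m, features_d = initial_features
    features_m = np.asarray(features_m, dtype=np.float64)
    features_d = np.asarray(features_d, dtype=np.float64)
    if features_m.shape[0] != network.n_metabolites or features_d.shape[0] != network.n_diseases:
        raise ValueError("feature row counts must match the network partitions")
    if features_m.shape[1] != features_d.shape[1]:
        raise ValueError("metabolite and disease features must share their dimension")

    if not cfg.use_nmf_features:
        # "w/o n" ablation: seeded uniform features of the same shape
        rng = np.random.default_rng(derive_seed(cfg.seed, "features"))
        features_m = rng.random(features_m.shape)
        features_d = rng.random(features_d.shape)

    tau = cfg.tau if cfg.use_masking else 0.0
    loss_weight = cfg.loss_weight if cfg.use_degree_decoder else 0.0

    model = GAEModel(
        encoder_config,
        decoder_config,
        feature_dim=features_m.shape[1],
        seed=derive_seed(cfg.seed, "params"),
    )
    optimizer = Adam(model.parameters(), learning_rate=cfg.learning_rate)

    U = network.n_metabolites
    X = np.vstack([features_m, features_d])
    positives = network.edge_index_pairs()
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("cannot train on a network with no associations")
    deg_m, deg_d = node_degrees(network)
    true_degrees = np.concatenate([deg_m, deg_d]).astype(np.float64)
    positive_set = {(int(i), int(j)) for i, j in positives}
    n_neg = max(1, round(cfg.negative_ratio * n_pos))

    trace: list[dict] = []
    for epoch in range(cfg.epochs):
        split = mask_edges(network, tau, seed=derive_seed(cfg.seed, "mask", epoch))
        negatives = sample_negative_pairs(
            network, n_neg, seed=derive_seed(cfg.seed, "negatives", epoch)
        )
        neg_arr = np.array(sorted(negatives), dtype=np.intp).reshape(-1, 2)
        m_idx = np.concatenate([positives[:, 0], neg_arr[:, 0]])
        d_idx = np.concatenate([positives[:, 1], neg_arr[:, 1]])
        labels = np.concatenate([np.ones(n_pos), np.zeros(len(neg_arr))])

        H = model.encode_tensor(Tensor(X), _reserved_adjacency(network, split))
        scores = model.edge_scores_tensor(H, U, m_idx, d_idx)
        l_edge = _bce_tensor(scores, labels)
        pred_deg = model.degree_tensor(H)
        l_degree = (Tensor(true_degrees) - pred_deg).square().mean()
        loss = l_edge + loss_weight * l_degree

        record = {
            "epoch": epoch,
            "edge_loss": float(l_edge.value),
            "degree_loss": float(l_degree.value),
            "total_loss": float(loss.value),
        }
        if not np.isfinite(record["total_loss"]):
            raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
        trace.append(record)

        optimizer.zero_grad()
        loss.backward()
        optimizer.step()

    embeddings = model.embeddings(network, features_m, features_d, split=None)
    return TrainResult(model, embeddings, tuple(trace))
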