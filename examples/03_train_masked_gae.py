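"""Train the Bernoulli-masked graph autoencoder and score candidate pairs.

Each epoch hides a fresh 40% of the observed edges from message passing,
reconstructs all observed edges (masked included) against 1:1 resampled
negatives, and regresses every node's degree as an auxiliary task.
"""

import numpy as np

from mdgae import (
    NMFConfig,
    PlantedConfig,
    TrainingConfig,
    factorize,
    generate_planted_network,
    node_features,
    score_all_pairs,
    train,
)

network, _ = generate_planted_network(
    PlantedConfig(U=120, V=30, true_rank=4, density=0.08, seed=42)
)
factors, _ = factorize(network, NMFConfig(K=12, seed=0))
result = train(
    network,
    node_features(factors),
    training_config=TrainingConfig(epochs=150, seed=0),
)

first, last = result.loss_trace[0], result.loss_trace[-1]
print(f"loss: {first['total_loss']:.3f} -> {last['total_loss']:.3f} over 150 epochs")
print(f"  edge reconstruction: {first['edge_loss']:.3f} -> {last['edge_loss']:.3f}")
print(f"  degree regression:   {first['degree_loss']:.3f} -> {last['degree_loss']:.3f}")

table = score_all_pairs(
    result.embeddings, result.model, result.model.decoder_config, network
)
observed = table.scores[network.adjacency == 1]
unknown = table.scores[network.adjacency == 0]
print(f"mean score on observed pairs: {observed.mean():.3f}")
print(f"mean score on unknown pairs:  {unknown.mean():.3f}")
# A trained model separates the two populations; unknown pairs with high
# scores are the discovery candidates.
print(f"top unknown-pair score: {unknown.max():.3f}")
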