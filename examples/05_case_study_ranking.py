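"""Leave-disease-out case-study protocol.

Every edge of one disease is hidden from the entire pipeline (NMF and
autoencoder), the model is retrained, and the disease's candidate
metabolites are ranked.  This emulates asking the model about a disease with
no curated metabolite associations at all - the hardest cold-start setting.
"""

import numpy as np

from mdgae import NMFConfig, PlantedConfig, TrainingConfig, generate_planted_network, leave_disease_out

network, _ = generate_planted_network(
    PlantedConfig(U=120, V=30, true_rank=4, density=0.08, seed=42)
)
degrees = network.adjacency.sum(axis=0)
target = network.disease_ids[int(degrees.argmax())]
true_partners = {
    network.metabolite_ids[i]
    for i in np.flatnonzero(network.adjacency[:, network.disease_index(target)])
}

ranked = leave_disease_out(
    network,
    target,
    NMFConfig(K=12, seed=0),
    training_config=TrainingConfig(epochs=150, seed=0),
    top_k=20,
)
print(f"disease {target} ({len(true_partners)} true partners, all hidden from training)")
print("rank  metabolite  score  true-partner?")
for r, (metabolite, score) in enumerate(ranked, start=1):
    marker = "yes" if metabolite in true_partners else ""
    print(f"{r:4d}  {metabolite:10s}  {score:.3f}  {marker}")
# With all of the disease's edges removed, its initial feature vector is
# zero, so recovery must come from global network structure alone; see
# docs/methods.md for why this cold-start setting is fundamentally hard.
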