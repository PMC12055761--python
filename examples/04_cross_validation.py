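"""Evaluate the full pipeline with k-fold cross-validation.

Observed edges are split into folds; each fold's positives are removed from
training (NMF features are recomputed on the reduced network to avoid
leakage) and scored together with fixed, never-observed negative pairs.
"""

from mdgae import NMFConfig, PlantedConfig, TrainingConfig, cross_validate, generate_planted_network

network, _ = generate_planted_network(
    PlantedConfig(U=120, V=30, true_rank=4, density=0.08, noise_flip_rate=0.02, seed=42)
)
folds, mean = cross_validate(
    network,
    NMFConfig(K=12, seed=0),
    training_config=TrainingConfig(epochs=150, seed=0),
    k=5,
    seed=0,
)

print("fold  " + "  ".join(f"{name:>6s}" for name in mean.as_dict()))
for i, report in enumerate(folds):
    print(f"{i + 1:4d}  " + "  ".join(f"{v:6.3f}" for v in report.as_dict().values()))
print("mean  " + "  ".join(f"{v:6.3f}" for v in mean.as_dict().values()))
# AUC is the probability a held-out true association outscores a sampled
# non-association; AUPR weights the top of the ranking, which is what a
# laboratory following up predictions actually consumes.
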