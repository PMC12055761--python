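"""Generate a planted low-rank bipartite network and inspect its structure.

The generator plants a rank-r non-negative score matrix, keeps the top
U*V*density scores as edges, and optionally flips a fraction of all entries
to emulate curation noise.
"""

import numpy as np

from mdgae import PlantedConfig, generate_planted_network, node_degrees

config = PlantedConfig(
    U=120, V=30, true_rank=4, density=0.08, noise_flip_rate=0.02, seed=42
)
network, (m_true, d_true) = generate_planted_network(config)
deg_m, deg_d = node_degrees(network)

print(f"network: {network.n_metabolites} metabolites x {network.n_diseases} diseases")
print(f"edges: {network.n_edges} (clean target was {int(120 * 30 * 0.08)};")
print("        the difference is the flip noise adding/removing associations)")
print(f"metabolite degree: mean {deg_m.mean():.2f}, max {deg_m.max()}")
print(f"disease degree:    mean {deg_d.mean():.2f}, max {deg_d.max()}")
print(f"planted score matrix rank: {np.linalg.matrix_rank(m_true @ d_true)}")
# The degree vectors always sum to the edge count - the first invariant every
# downstream stage relies on.
assert deg_m.sum() == deg_d.sum() == network.n_edges
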