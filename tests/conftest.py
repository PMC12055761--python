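import numpy as np
import pytest

from mdgae import AssociationNetwork, PlantedConfig, generate_planted_network


@pytest.fixture
def tiny_network() -> AssociationNetwork:
    """3 metabolites x 2 diseases, 4 edges, built by hand."""
    adjacency = np.array([[1, 1], [0, 1], [1, 0]], dtype=np.int8)
    return AssociationNetwork(("mA", "mB", "mC"), ("dX", "dY"), adjacency)


@pytest.fixture
def random_network() -> AssociationNetwork:
    """Seeded 10x6 network with exactly 20 edges."""
    rng = np.random.default_rng(42)
    adjacency = np.zeros(60, dtype=np.int8)
    adjacency[rng.choice(60, size=20, replace=False)] = 1
    ids_m = tuple(f"m{i:02d}" for i in range(10))
    ids_d = tuple(f"d{i}" for i in range(6))
    return AssociationNetwork(ids_m, ids_d, adjacency.reshape(10, 6))


@pytest.fixture(scope="session")
def planted_noiseless():
    """Clean planted network used by the NMF recovery checks."""
    config = PlantedConfig(U=60, V=30, true_rank=3, density=0.2, seed=11)
    network, factors = generate_planted_network(config)
    return config, network, factors


@pytest.fixture(scope="session")
def planted_small():
    """Small planted network for fast end-to-end training tests."""
    config = PlantedConfig(U=40, V=16, true_rank=3, density=0.12, seed=5)
    network, factors = generate_planted_network(config)
    return config, network, factors
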