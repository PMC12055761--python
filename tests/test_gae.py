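import numpy as np
import pytest
from oracles import gin_encode_oracle

from mdgae import (
    AssociationNetwork,
    DecoderConfig,
    EncoderConfig,
    GAEModel,
    NodeEmbeddings,
    PlantedConfig,
    TrainingConfig,
    bce_edge_loss,
    degree_loss,
    degree_predict,
    edge_score,
    encode,
    generate_planted_network,
    mask_edges,
    sample_negative_pairs,
    total_loss,
    train,
)
from mdgae.gae import SamplingError, _reserved_adjacency


def _identity_gin_model(dim: int, eps: float = 0.0) -> GAEModel:
    """Two GIN layers whose MLPs are exact identities (for closed-form checks)."""
    config = EncoderConfig(variant="GIN", layer_dims=(dim, dim), eps_init=eps)
    model = GAEModel(config, DecoderConfig(), feature_dim=dim, seed=0)
    for layer in model.encoder_layers:
        (W1, b1), (W2, b2) = layer["mlp"]
        W1.value = np.eye(dim)
        W2.value = np.eye(dim)
        b1.value[:] = 0
        b2.value[:] = 0
    return model


class TestMaskEdges:
    @pytest.mark.parametrize("tau,expect", [(0.0, "none"), (1.0, "all")])
    def test_degenerate_rates(self, random_network, tau, expect):
        split = mask_edges(random_network, tau, seed=0)
        if expect == "none":
            assert not split.masked_edges
            assert len(split.reserved_edges) == random_network.n_edges
        else:
            assert not split.reserved_edges
            assert len(split.masked_edges) == random_network.n_edges

    def test_partition_over_seeds_and_rates(self, random_network):
        all_edges = {tuple(e) for e in random_network.edge_index_pairs()}
        for seed in range(100):
            for tau in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
                split = mask_edges(random_network, tau, seed=seed)
                assert split.masked_edges | split.reserved_edges == all_edges
                assert not split.masked_edges & split.reserved_edges

    def test_binomial_mean_at_default_rate(self):
        config = PlantedConfig(U=100, V=100, true_rank=4, density=0.1, seed=2)
        network, _ = generate_planted_network(config)
        n = network.n_edges
        assert n == 1000
        counts = [len(mask_edges(network, 0.4, seed=s).masked_edges) for s in range(500)]
        tolerance = 3 * np.sqrt(n * 0.4 * 0.6) / np.sqrt(500)
        assert abs(np.mean(counts) - 400) <= tolerance

    def test_invalid_rate(self, random_network):
        with pytest.raises(ValueError):
            mask_edges(random_network, 1.5, seed=0)


class TestEncoder:
    def test_single_edge_neighbor_sum_closed_form(self):
        # one metabolite, one disease, one edge; identity MLPs, eps = 0:
        # layer 1: H_a <- X_a + X_b ; layer 2 doubles it again
        network = AssociationNetwork(("m",), ("d",), np.array([[1]], dtype=np.int8))
        x_m = np.array([[1.0, 2.0, 0.5]])
        x_d = np.array([[0.25, 1.0, 3.0]])
        model = _identity_gin_model(3)
        split = mask_edges(network, 0.0, seed=0)
        emb = encode(network, split, (x_m, x_d), model.encoder_config, model)
        first = x_m + x_d  # both endpoints coincide after one layer
        np.testing.assert_allclose(emb.H_m[0], 2 * first[0])
        np.testing.assert_allclose(emb.H_d[0], 2 * first[0])

    def test_isolated_node_scaling_closed_form(self):
        # no edges reserved; eps = 0.5 -> each layer multiplies by 1.5
        network = AssociationNetwork(
            ("m1", "m2"), ("d1",), np.array([[1], [0]], dtype=np.int8)
        )
        x_m = np.array([[2.0, 4.0], [1.0, 3.0]])
        x_d = np.array([[0.0, 0.0]])
        model = _identity_gin_model(2, eps=0.5)
        split = mask_edges(network, 1.0, seed=0)  # everything masked
        emb = encode(network, split, (x_m, x_d), model.encoder_config, model)
        np.testing.assert_allclose(emb.H_m[1], 1.5**2 * x_m[1])

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(33)
        for trial in range(8):
            U, V = rng.integers(2, 6), rng.integers(2, 5)
            adjacency = (rng.random((U, V)) < 0.5).astype(np.int8)
            network = AssociationNetwork(
                tuple(f"m{i}" for i in range(U)),
                tuple(f"d{j}" for j in range(V)),
                adjacency,
            )
            config = EncoderConfig(variant="GIN", layer_dims=(5, 4))
            model = GAEModel(config, DecoderConfig(), feature_dim=3, seed=trial)
            x_m, x_d = rng.normal(size=(U, 3)), rng.normal(size=(V, 3))
            split = mask_edges(network, 0.3, seed=trial)
            emb = encode(network, split, (x_m, x_d), config, model)
            reserved = _reserved_adjacency(network, split)
            expected = gin_encode_oracle(np.vstack([x_m, x_d]), reserved, model)
            np.testing.assert_allclose(
                np.vstack([emb.H_m, emb.H_d]), expected, atol=1e-6
            )

    def test_masked_edges_excluded_from_message_passing(self, random_network):
        model = GAEModel(EncoderConfig(), DecoderConfig(), feature_dim=4, seed=1)
        rng = np.random.default_rng(0)
        feats = (rng.random((10, 4)), rng.random((6, 4)))
        split = mask_edges(random_network, 0.5, seed=3)
        emb_masked = encode(random_network, split, feats, model.encoder_config, model)
        # physically deleting the masked edges must give identical embeddings
        pruned = random_network.adjacency.copy()
        for i, j in split.masked_edges:
            pruned[i, j] = 0
        pruned_network = random_network.with_adjacency(pruned)
        full_split = mask_edges(pruned_network, 0.0, seed=0)
        emb_pruned = encode(
            pruned_network, full_split, feats, model.encoder_config, model
        )
        np.testing.assert_array_equal(emb_masked.H_m, emb_pruned.H_m)
        np.testing.assert_array_equal(emb_masked.H_d, emb_pruned.H_d)

    @pytest.mark.parametrize("variant", ["GCN", "GAT"])
    def test_alternative_encoders_run_and_are_finite(self, random_network, variant):
        config = EncoderConfig(variant=variant, layer_dims=(6, 4))
        model = GAEModel(config, DecoderConfig(), feature_dim=3, seed=2)
        rng = np.random.default_rng(1)
        feats = (rng.random((10, 3)), rng.random((6, 3)))
        split = mask_edges(random_network, 0.4, seed=1)
        emb = encode(random_network, split, feats, config, model)
        assert emb.H_m.shape == (10, 4) and emb.H_d.shape == (6, 4)


class TestEdgeScore:
    def test_hadamard_zero_embedding_absorbs(self):
        decoder = DecoderConfig(combiner="hadamard")
        model = GAEModel(EncoderConfig(), decoder, feature_dim=4, seed=0)
        H_d = np.zeros((1, 128))
        score_a = edge_score((0, 0), NodeEmbeddings(np.full((1, 128), 5.0), H_d), decoder, model)
        score_b = edge_score((0, 0), NodeEmbeddings(np.full((1, 128), -2.0), H_d), decoder, model)
        assert score_a == pytest.approx(score_b)

    def test_inner_orthogonal_gives_sigmoid_of_bias(self):
        decoder = DecoderConfig(combiner="inner")
        model = GAEModel(EncoderConfig(), decoder, feature_dim=4, seed=0)
        model.inner_bias.value = np.array(0.8)
        emb = NodeEmbeddings(np.array([[1.0, 0.0]]), np.array([[0.0, 2.0]]))
        expected = 1.0 / (1.0 + np.exp(-0.8))
        assert edge_score((0, 0), emb, decoder, model) == pytest.approx(expected)

    def test_hand_set_single_layer_sigmoid(self):
        decoder = DecoderConfig(combiner="hadamard", hidden_dims=())
        model = GAEModel(
            EncoderConfig(layer_dims=(4, 2)), decoder, feature_dim=2, seed=0
        )
        (W, b) = model.edge_layers[0]
        W.value = np.array([[0.5], [-1.0]])
        b.value = np.array([0.25])
        emb = NodeEmbeddings(np.array([[2.0, 1.0]]), np.array([[3.0, 4.0]]))
        z = 0.5 * (2 * 3) + (-1.0) * (1 * 4) + 0.25  # w . (hm * hd) + b
        assert edge_score((0, 0), emb, decoder, model) == pytest.approx(
            1.0 / (1.0 + np.exp(-z))
        )

    def test_out_of_range_pair(self):
        decoder = DecoderConfig()
        model = GAEModel(EncoderConfig(), decoder, feature_dim=2, seed=0)
        emb = NodeEmbeddings(np.ones((2, 128)), np.ones((3, 128)))
        with pytest.raises(IndexError):
            edge_score((2, 0), emb, decoder, model)


class TestLosses:
    def test_bce_uniform_scores(self):
        assert bce_edge_loss([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(np.log(2))

    def test_bce_perfect_prediction_near_zero(self):
        assert bce_edge_loss([1.0, 0.0], [1, 0]) <= -np.log(1 - 1e-7) + 1e-12

    def test_bce_label_symmetry(self):
        for s in (0.1, 0.35, 0.8):
            assert bce_edge_loss([s], [1]) == pytest.approx(bce_edge_loss([1 - s], [0]))

    def test_degree_loss_values(self):
        assert degree_loss([2.0, 4.0], [2.0, 4.0]) == 0.0
        assert degree_loss([3.0, 3.0], [2.0, 4.0]) == pytest.approx(1.0)

    def test_degree_loss_quadratic_homogeneity(self):
        base = degree_loss([1.0, -1.0], [0.0, 0.0])
        scaled = degree_loss([3.0, -3.0], [0.0, 0.0])
        assert scaled == pytest.approx(9 * base)

    def test_total_loss(self):
        assert total_loss(0.5, 0.25, 0.0) == 0.5
        assert total_loss(0.5, 0.25, 1.0) == pytest.approx(0.75)
        assert TrainingConfig().loss_weight == 0.6

    def test_length_mismatches(self):
        with pytest.raises(ValueError):
            bce_edge_loss([0.5], [1, 0])
        with pytest.raises(ValueError):
            degree_loss([1.0], [1.0, 2.0])


class TestDegreePredict:
    def test_identical_embeddings_identical_predictions(self):
        model = GAEModel(
            EncoderConfig(layer_dims=(4, 2)), DecoderConfig(), feature_dim=2, seed=0
        )
        emb = NodeEmbeddings(
            np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]), np.array([[1.0, 2.0]])
        )
        predicted = degree_predict(emb, model)
        assert predicted.shape == (4,)
        assert np.allclose(predicted, predicted[0])

    def test_hand_set_affine_output(self):
        decoder = DecoderConfig(degree_decoder_hidden=())
        model = GAEModel(
            EncoderConfig(layer_dims=(4, 2)), decoder, feature_dim=2, seed=0
        )
        (W, b) = model.degree_layers[0]
        W.value = np.array([[2.0], [-0.5]])
        b.value = np.array([1.0])
        emb = NodeEmbeddings(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]]))
        predicted = degree_predict(emb, model)
        assert predicted[0] == pytest.approx(2.0 * 3 - 0.5 * 4 + 1.0)
        assert predicted[1] == pytest.approx(1.0)


class TestSampleNegativePairs:
    def test_all_pairs_unobserved(self, random_network):
        pairs = sample_negative_pairs(random_network, 15, seed=4)
        for i, j in pairs:
            assert random_network.adjacency[i, j] == 0

    def test_determinism_and_exclusion(self, random_network):
        a = sample_negative_pairs(random_network, 10, seed=5)
        b = sample_negative_pairs(random_network, 10, seed=5)
        assert a == b
        c = sample_negative_pairs(random_network, 10, seed=6, exclude=a)
        assert not a & c

    def test_saturated_network_errors(self):
        network = AssociationNetwork(("m",), ("d",), np.array([[1]], dtype=np.int8))
        with pytest.raises(SamplingError):
            sample_negative_pairs(network, 1, seed=0)


class TestTrain:
    def test_deterministic_loss_trace(self, planted_small):
        _, network, _ = planted_small
        rng = np.random.default_rng(0)
        feats = (rng.random((network.n_metabolites, 4)), rng.random((network.n_diseases, 4)))
        cfg = TrainingConfig(epochs=8, seed=12)
        trace_a = train(network, feats, training_config=cfg).loss_trace
        trace_b = train(network, feats, training_config=cfg).loss_trace
        assert trace_a == trace_b

    def test_ablation_flags(self, planted_small):
        _, network, _ = planted_small
        rng = np.random.default_rng(1)
        feats = (rng.random((network.n_metabolites, 4)), rng.random((network.n_diseases, 4)))
        base = dict(epochs=5, seed=3)
        # w/o m: disabling masking is identical to tau = 0
        no_mask = train(
            network, feats, training_config=TrainingConfig(use_masking=False, **base)
        ).loss_trace
        tau_zero = train(
            network, feats, training_config=TrainingConfig(tau=0.0, **base)
        ).loss_trace
        assert no_mask == tau_zero
        # w/o d: disabling the degree decoder is identical to weight 0 in total loss
        no_degree = train(
            network,
            feats,
            training_config=TrainingConfig(use_degree_decoder=False, **base),
        ).loss_trace
        assert all(
            rec["total_loss"] == pytest.approx(rec["edge_loss"]) for rec in no_degree
        )
        # w/o n: replacement features change the trace
        no_nmf = train(
            network,
            feats,
            training_config=TrainingConfig(use_nmf_features=False, **base),
        ).loss_trace
        assert no_nmf != train(network, feats, training_config=TrainingConfig(**base)).loss_trace

    def test_loss_decreases_on_planted_network(self):
        config = PlantedConfig(U=200, V=40, true_rank=5, density=0.05, seed=31)
        network, _ = generate_planted_network(config)
        from mdgae import NMFConfig, factorize, node_features

        factors, _ = factorize(network, NMFConfig(K=8, max_iterations=150, seed=1))
        feats = node_features(factors)
        result = train(
            network, feats, training_config=TrainingConfig(epochs=200, seed=2)
        )
        assert result.loss_trace[-1]["total_loss"] < result.loss_trace[0]["total_loss"]
        assert all(np.isfinite(rec["total_loss"]) for rec in result.loss_trace)
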