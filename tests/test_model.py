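"""The attention network: attention math, layer forward, full model,
training, prediction and checkpointing."""

import numpy as np
import pytest

from conftest import dense_gat_oracle, random_graph, random_layer
from mslgat import autodiff as ad
from mslgat.graph import adjacency
from mslgat.model import (HeadParams, ModelConfig, _Adam, _param_arrays,
                          aggregate_neighborhood, attention_coefficients,
                          compute_loss_and_grads, dense_block_forward,
                          forward_pass, gat_layer_forward, init_params,
                          load_checkpoint, predict_scores, save_checkpoint,
                          train_model, weighted_multihead)
from mslgat.simulate import SyntheticSpec, generate_planted_graph

SCALAR_HEAD = HeadParams(W=np.array([[1.0]]), a_self=np.array([1.0]),
                         a_neigh=np.array([1.0]))


class TestAttention:
    def test_scalar_toy_matches_hand_computation(self):
        h = np.array([[1.0], [2.0], [3.0]])
        alpha = attention_coefficients(h, SCALAR_HEAD, [1, 2], 0)
        # e = (1+2, 1+3) = (3, 4) -> softmax = (0.2689, 0.7311)
        np.testing.assert_allclose(alpha, [0.26894142, 0.73105858], atol=1e-6)

    def test_singleton_neighborhood_is_certain(self):
        alpha = attention_coefficients(np.array([[2.0]]), SCALAR_HEAD, [0], 0)
        np.testing.assert_allclose(alpha, [1.0])

    def test_identical_neighbors_share_attention(self):
        h = np.array([[1.0], [5.0], [5.0]])
        alpha = attention_coefficients(h, SCALAR_HEAD, [1, 2], 0)
        np.testing.assert_allclose(alpha, [0.5, 0.5])

    def test_empty_neighborhood_suggests_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            attention_coefficients(np.array([[1.0]]), SCALAR_HEAD, [], 0)

    def test_rows_sum_to_one_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 31))
            edges, a = random_graph(rng, n, 0.3)
            head = HeadParams(W=rng.normal(size=(3, 4)),
                              a_self=rng.normal(size=4), a_neigh=rng.normal(size=4))
            h = rng.normal(size=(n, 3))
            dense = a.toarray()
            for i in range(n):
                alpha = attention_coefficients(h, head, np.flatnonzero(dense[i]), i)
                assert abs(alpha.sum() - 1.0) < 1e-6


class TestAggregation:
    def test_one_hot_attention_copies_neighbor(self, rng):
        h = rng.normal(size=(4, 3))
        head = HeadParams(W=np.eye(3), a_self=np.zeros(3), a_neigh=np.zeros(3))
        out = aggregate_neighborhood(np.array([0.0, 1.0]), head, h, [1, 2])
        np.testing.assert_allclose(out, h[2])

    def test_scalar_toy_aggregate(self):
        h = np.array([[1.0], [2.0], [3.0]])
        alpha = attention_coefficients(h, SCALAR_HEAD, [1, 2], 0)
        out = aggregate_neighborhood(alpha, SCALAR_HEAD, h, [1, 2])
        np.testing.assert_allclose(out, [2.73105858], atol=1e-6)

    def test_zero_states_give_sigma_zero(self):
        h = np.zeros((2, 1))
        out = aggregate_neighborhood(np.array([1.0]), SCALAR_HEAD, h, [1],
                                     activation=lambda x: x + 7)
        np.testing.assert_allclose(out, [7.0])


class TestWeightedMultihead:
    HEADS = [[0.2, 0.4, 0.6], [0.1, 0.5, 0.7], [0.3, 0.3, 0.4], [0.4, 0.2, 0.5]]

    def test_four_head_weighted_average(self):
        out = weighted_multihead(self.HEADS, [0.5, 1 / 6, 1 / 6, 1 / 6])
        np.testing.assert_allclose(out, [0.7 / 3, 1.1 / 3, 1.7 / 3], atol=1e-12)
        assert round(out[0], 4) == 0.2333
        assert np.floor(out[1] * 1000) / 1000 == 0.366
        assert np.floor(out[2] * 1000) / 1000 == 0.566

    def test_one_hot_weights_select_single_head(self):
        out = weighted_multihead(self.HEADS, [0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(out, self.HEADS[2])

    def test_identical_outputs_invariant_to_weights(self, rng):
        same = [[1.0, 2.0]] * 4
        w = rng.dirichlet(np.ones(4))
        np.testing.assert_allclose(weighted_multihead(same, w), [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_multihead([[1.0], [1.0, 2.0]], [0.5, 0.5])

    def test_non_simplex_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_multihead([[1.0], [2.0]], [0.9, 0.9])


class TestGatLayer:
    def test_matches_dense_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 21))
            k = int(rng.integers(1, 5))
            edges, a = random_graph(rng, n, 0.4)
            layer = random_layer(rng, 3, 5, k)
            h = rng.normal(size=(n, 3))
            ours = gat_layer_forward(h, a, layer)
            oracle = dense_gat_oracle(h, a, layer)
            np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        n = 8
        edges, a = random_graph(rng, n, 0.4)
        layer = random_layer(rng, 3, 4, 2)
        h = rng.normal(size=(n, 3))
        perm = rng.permutation(n)
        p = np.eye(n)[perm]
        out = gat_layer_forward(h, a, layer)
        out_p = gat_layer_forward(p @ h, p @ a.toarray() @ p.T, layer)
        np.testing.assert_allclose(out_p, p @ out, atol=1e-8)

    def test_single_node_reduces_to_per_node_transform(self, rng):
        layer = random_layer(rng, 3, 4, 2)
        a = adjacency(1, np.empty((0, 2)), self_loops=True)
        h = rng.normal(size=(1, 3))
        expected = sum(w * (h @ head.W)
                       for w, head in zip(layer.head_weights(), layer.heads))
        np.testing.assert_allclose(gat_layer_forward(h, a, layer), expected,
                                   atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        layer = random_layer(rng, 3, 4, 2)
        a = adjacency(2, np.array([[0, 1]]))
        with pytest.raises(ValueError):
            gat_layer_forward(rng.normal(size=(2, 5)), a, layer)


def _fitted(params, graph, config):
    """Run one train-mode pass so BN running statistics exist."""
    a = adjacency(graph.n_nodes, graph.edges)
    forward_pass(graph.X, a, params, mode="train", seed=0)
    return a


class TestForwardPass:
    @pytest.fixture()
    def setup(self, small_planted_graph, tiny_config):
        params = init_params(small_planted_graph.n_features, tiny_config)
        a = _fitted(params, small_planted_graph, tiny_config)
        return params, small_planted_graph, a

    def test_probabilities_strictly_inside_unit_interval(self, setup):
        params, graph, a = setup
        probs, _ = forward_pass(graph.X, a, params, mode="eval")
        assert probs.shape == (graph.n_nodes,)
        assert (probs > 0).all() and (probs < 1).all()

    def test_eval_mode_is_bitwise_deterministic(self, setup):
        params, graph, a = setup
        p1, _ = forward_pass(graph.X, a, params, mode="eval")
        p2, _ = forward_pass(graph.X, a, params, mode="eval")
        np.testing.assert_array_equal(p1, p2)

    def test_zeroed_second_layer_makes_residual_an_identity(self, setup):
        params, graph, a = setup
        for head in params.gat2.heads:
            head.W[:] = 0
            head.a_self[:] = 0
            head.a_neigh[:] = 0
        _, trace = forward_pass(graph.X, a, params, mode="eval")
        np.testing.assert_array_equal(trace.total_h2, 0.0)
        np.testing.assert_array_equal(trace.h_residual, trace.total_h1)

    def test_permutation_equivariance_in_eval_mode(self, setup, rng):
        params, graph, a = setup
        probs, _ = forward_pass(graph.X, a, params, mode="eval")
        perm = rng.permutation(graph.n_nodes)
        p = np.eye(graph.n_nodes)[perm]
        probs_p, _ = forward_pass(p @ graph.X, p @ a.toarray() @ p.T,
                                  params, mode="eval")
        np.testing.assert_allclose(probs_p, p @ probs, atol=1e-5)

    def test_eval_before_fitting_bn_raises(self, small_planted_graph, tiny_config):
        params = init_params(small_planted_graph.n_features, tiny_config)
        a = adjacency(small_planted_graph.n_nodes, small_planted_graph.edges)
        with pytest.raises(RuntimeError, match="unfitted"):
            forward_pass(small_planted_graph.X, a, params, mode="eval")

    def test_shape_mismatch_rejected(self, setup):
        params, graph, a = setup
        with pytest.raises(ValueError):
            forward_pass(graph.X[:-1], a, params, mode="eval")


class TestDenseBlock:
    def test_final_block_zero_weights_give_half(self):
        from mslgat.model import DenseBlockParams
        block = DenseBlockParams(np.zeros((3, 1)), np.zeros(1), None, 0.0,
                                 is_final=True)
        out = dense_block_forward(np.array([1.0, -2.0, 3.0]), block)
        np.testing.assert_allclose(out, [[0.5]])

    def test_non_final_arithmetic_with_identity_bn(self):
        from mslgat.model import BatchNormParams, DenseBlockParams
        bn = BatchNormParams.create(1)
        bn.fitted = True  # running mean 0, var 1: effectively identity
        block = DenseBlockParams(np.array([[2.0]]), np.array([1.0]), bn, 0.0)
        out = dense_block_forward(np.array([3.0]), block, mode="eval")
        np.testing.assert_allclose(out, [[7.0]], atol=1e-4)

    def test_eval_mode_repeatable(self, rng):
        from mslgat.model import BatchNormParams, DenseBlockParams
        bn = BatchNormParams.create(2)
        bn.fitted = True
        block = DenseBlockParams(rng.normal(size=(3, 2)), rng.normal(size=2),
                                 bn, 0.5)
        x = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(dense_block_forward(x, block),
                                      dense_block_forward(x, block))


class TestRegularizers:
    def test_dropout_zeroes_about_half_the_entries(self):
        rng = np.random.default_rng(5)
        x = ad.Tensor(np.ones((100, 100)))
        dropped = ad.dropout(x, 0.5, rng)
        frac = (dropped.value == 0).mean()
        # 99% binomial interval around 0.5 for n = 10000
        assert abs(frac - 0.5) < 2.576 * np.sqrt(0.25 / 10000)
        kept = dropped.value[dropped.value != 0]
        np.testing.assert_allclose(kept, 2.0)  # inverted scaling

    def test_batchnorm_train_mode_standardizes(self):
        from mslgat.model import BatchNormParams, _bn_t
        rng = np.random.default_rng(6)
        x = rng.normal(3.0, 2.5, size=(5000, 4))
        bn = BatchNormParams.create(4)
        out = _bn_t(ad.Tensor(x), bn, ad.Tensor(bn.gamma), ad.Tensor(bn.beta),
                    "train", update_running=True).value
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-3)
        np.testing.assert_allclose(out.var(axis=0), 1.0, atol=1e-3)
        assert bn.fitted


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = ModelConfig(d1=5, d2=5, d3=4, dense_dims=(6, 3), heads=2,
                          dropout=0.0, epochs=1, seed=3)
        params = init_params(4, cfg)
        graph = generate_planted_graph(SyntheticSpec(
            n_nodes=6, n_features=4, driver_fraction=0.5, edge_prob=0.5, seed=2))
        a = adjacency(6, graph.edges)
        mask = np.ones(6, bool)
        y = graph.labels.astype(float)
        _, grads, _ = compute_loss_and_grads(params, graph.X, a, mask, y,
                                             "train", None, update_running=False)
        arrays = _param_arrays(params)
        h = 1e-6
        for name, arr in arrays.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp, _, _ = compute_loss_and_grads(params, graph.X, a, mask, y,
                                                  "train", None, update_running=False)
                arr[idx] = orig - h
                lm, _, _ = compute_loss_and_grads(params, graph.X, a, mask, y,
                                                  "train", None, update_running=False)
                arr[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = grads[name][idx] if grads[name] is not None else 0.0
                assert abs(fd - an) < 1e-4, f"{name}{idx}: fd={fd} analytic={an}"


class TestTraining:
    def test_zero_epochs_returns_initialization(self, small_planted_graph, tiny_config):
        cfg = ModelConfig(**{**tiny_config.__dict__, "epochs": 0})
        params, report = train_model(small_planted_graph, cfg)
        init = init_params(small_planted_graph.n_features, cfg)
        for name, arr in _param_arrays(params).items():
            np.testing.assert_array_equal(arr, _param_arrays(init)[name])
        assert report.train_loss == [] and report.best_epoch == -1

    def test_loss_decreases_on_separable_graph(self, small_planted_graph, tiny_config):
        cfg = ModelConfig(**{**tiny_config.__dict__, "epochs": 50, "dropout": 0.5})
        _, report = train_model(small_planted_graph, cfg)
        assert report.train_loss[-1] < report.train_loss[0]

    def test_identical_seed_gives_identical_report(self, small_planted_graph, tiny_config):
        _, r1 = train_model(small_planted_graph, tiny_config)
        _, r2 = train_model(small_planted_graph, tiny_config)
        assert r1.train_loss == r2.train_loss
        assert r1.val_loss == r2.val_loss
        assert r1.best_epoch == r2.best_epoch

    def test_head_weights_stay_on_simplex_during_training(self, small_planted_graph,
                                                          tiny_config):
        params = init_params(small_planted_graph.n_features, tiny_config)
        a = adjacency(small_planted_graph.n_nodes, small_planted_graph.edges)
        opt = _Adam(1e-2)
        arrays = _param_arrays(params)
        y = small_planted_graph.labels.astype(float)
        for step in range(5):
            _, grads, _ = compute_loss_and_grads(
                params, small_planted_graph.X, a, small_planted_graph.train_mask,
                y, "train", np.random.default_rng(step))
            opt.step(arrays, grads)
            for layer in (params.gat1, params.gat2, params.gat3):
                w = layer.head_weights()
                assert (w >= 0).all() and abs(w.sum() - 1.0) < 1e-12

    def test_single_class_training_labels_rejected(self, small_planted_graph,
                                                   tiny_config):
        graph = small_planted_graph
        labels = np.where(graph.labels == 1, 0, 0)
        from mslgat.graph import PatientGraph
        bad = PatientGraph(nodes=graph.nodes, edges=graph.edges, X=graph.X,
                           labels=labels, train_mask=graph.train_mask,
                           val_mask=graph.val_mask, test_mask=graph.test_mask)
        with pytest.raises(ValueError, match="both classes"):
            train_model(bad, tiny_config)


@pytest.fixture(scope="module")
def trained(small_planted_graph, tiny_config):
    return train_model(small_planted_graph, tiny_config)


class TestPredictAndCheckpoint:
    def test_one_row_per_node_and_threshold_rule(self, trained, small_planted_graph):
        params, _ = trained
        scores = predict_scores(params, small_planted_graph)
        assert len(scores) == small_planted_graph.n_nodes
        np.testing.assert_array_equal(
            scores["label"].to_numpy(),
            (scores["probability"].to_numpy() >= 0.5).astype(int))

    def test_feature_mismatch_rejected(self, trained, tiny_config):
        params, _ = trained
        bad = generate_planted_graph(SyntheticSpec(n_nodes=20, n_features=5, seed=1))
        with pytest.raises(ValueError, match="features"):
            predict_scores(params, bad)

    def test_checkpoint_round_trip_preserves_predictions(self, trained,
                                                         small_planted_graph,
                                                         tmp_path):
        params, _ = trained
        save_checkpoint(params, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        p1 = predict_scores(params, small_planted_graph)["probability"]
        p2 = predict_scores(loaded, small_planted_graph)["probability"]
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())
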