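"""GIN layers, attention pooling, readout and the full forward/backward."""

import numpy as np
import pytest

from connectogin import (
    GinClassifier,
    ModelConfig,
    attention_pool,
    gin_aggregate,
    init_state,
    load_state,
    readout_predict,
    save_state,
)

from conftest import random_adjacency


def identity_mlp_model(n: int, n_layers: int = 1) -> GinClassifier:
    """A model whose per-layer MLPs are the identity map (hidden_dim = n,
    no batch norm, weights set to I, biases 0); inputs must be nonnegative
    so the ReLUs are transparent."""
    cfg = ModelConfig(input_dim=n, n_layers=n_layers, hidden_dim=n,
                      dropout_rate=0.0, batch_norm=False, dtype="float64")
    model = GinClassifier(cfg, seed=0)
    for k in range(n_layers):
        for j in range(cfg.mlp_depth):
            model.state.params[f"gin{k}.lin{j}.W"] = np.eye(n)
            model.state.params[f"gin{k}.lin{j}.b"] = np.zeros(n)
    return model


class TestGinLayer:
    def test_two_node_hand_expansion(self):
        w = 0.7
        adj = np.array([[0.0, w], [w, 0.0]])
        h = np.eye(2)
        np.testing.assert_allclose(gin_aggregate(h, adj, eps=0.0),
                                   [[1.0, w], [w, 1.0]])
        model = identity_mlp_model(2)
        _, _, cache = model.forward(adj, keep_cache=True)
        np.testing.assert_allclose(cache["layers"][0]["x"],
                                   [[[1.0, w], [w, 1.0]]], atol=1e-12)

    def test_zero_weights_leave_input_unchanged(self):
        n = 4
        model = identity_mlp_model(n)
        _, _, cache = model.forward(np.zeros((n, n)), keep_cache=True)
        np.testing.assert_allclose(cache["layers"][0]["x"], [np.eye(n)],
                                   atol=1e-12)

    def test_isolated_node_gets_only_self_term(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.5  # node 2 isolated
        h = np.arange(6, dtype=float).reshape(3, 2)
        out = gin_aggregate(h, adj, eps=0.25)
        np.testing.assert_allclose(out[2], 1.25 * h[2])

    def test_matches_brute_force_message_passing(self, rng):
        n = 5
        adj = random_adjacency(rng, n, density=0.6)
        h = rng.standard_normal((n, 3))
        eps = 0.3
        expected = np.empty_like(h)
        for v in range(n):
            agg = (1 + eps) * h[v].copy()
            for u in range(n):
                if adj[v, u] != 0:
                    agg = agg + adj[v, u] * h[u]
            expected[v] = agg
        np.testing.assert_allclose(gin_aggregate(h, adj, eps), expected,
                                   atol=1e-6)


class TestAttentionPool:
    def test_single_node_is_identity(self, rng):
        x = rng.standard_normal((1, 4))
        g, s = attention_pool(x, rng.standard_normal((4, 4)), np.zeros(4))
        np.testing.assert_allclose(g, x[0], atol=1e-12)
        np.testing.assert_allclose(s, np.ones((1, 4)))

    def test_constant_gate_gives_column_mean(self, rng):
        x = rng.standard_normal((6, 3))
        g, s = attention_pool(x, np.zeros((3, 3)), np.zeros(3))
        np.testing.assert_allclose(g, x.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(s, np.full((6, 3), 1 / 6))

    def test_matches_brute_force_softmax_weighted_sum(self, rng):
        x = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        g, s = attention_pool(x, w, b)
        f = x @ w + b
        for j in range(3):
            e = np.exp(f[:, j])
            sm = e / e.sum()
            np.testing.assert_allclose(s[:, j], sm, atol=1e-6)
            np.testing.assert_allclose(g[j], (sm * x[:, j]).sum(), atol=1e-6)

    def test_gate_columns_sum_to_one(self, rng):
        x = rng.standard_normal((9, 5)) * 3
        _, s = attention_pool(x, rng.standard_normal((5, 5)),
                              rng.standard_normal(5))
        np.testing.assert_allclose(s.sum(axis=0), np.ones(5), atol=1e-6)

    def test_empty_graph_rejected(self, rng):
        with pytest.raises(ValueError, match="at least one node"):
            attention_pool(np.empty((0, 3)), np.eye(3), np.zeros(3))


class TestReadout:
    def test_zero_maps_give_bias_sum(self):
        cfg = ModelConfig(input_dim=4, n_layers=3, hidden_dim=2,
                          dropout_rate=0.0, dtype="float64")
        state = init_state(cfg, seed=0)
        for k in range(3):
            state.params[f"read{k}.W"][:] = 0.0
            state.params[f"read{k}.b"][:] = [0.1 * (k + 1), -0.2]
        logits = readout_predict([np.ones(2)] * 3, state)
        np.testing.assert_allclose(logits, [0.6, -0.6], atol=1e-12)

    def test_single_layer_reduces_to_linear_classifier(self, rng):
        cfg = ModelConfig(input_dim=4, n_layers=1, hidden_dim=3,
                          dropout_rate=0.0, dtype="float64")
        state = init_state(cfg, seed=1)
        g = rng.standard_normal(3)
        expected = g @ state.params["read0.W"] + state.params["read0.b"]
        np.testing.assert_allclose(readout_predict([g], state), expected)

    def test_two_layer_hand_arithmetic(self, rng):
        cfg = ModelConfig(input_dim=4, n_layers=2, hidden_dim=2,
                          dropout_rate=0.0, dtype="float64")
        state = init_state(cfg, seed=2)
        w1 = np.array([[1.0, -1.0], [0.5, 2.0]])
        w2 = np.array([[0.0, 3.0], [1.0, 1.0]])
        state.params["read0.W"], state.params["read1.W"] = w1, w2
        state.params["read0.b"] = np.array([0.1, 0.2])
        state.params["read1.b"] = np.array([-0.3, 0.0])
        g1, g2 = np.array([1.0, 2.0]), np.array([-1.0, 0.5])
        expected = g1 @ w1 + [0.1, 0.2] + g2 @ w2 + [-0.3, 0.0]
        np.testing.assert_allclose(readout_predict([g1, g2], state), expected)

    def test_wrong_layer_count_rejected(self, rng):
        cfg = ModelConfig(input_dim=4, n_layers=2, hidden_dim=2)
        state = init_state(cfg, seed=0)
        with pytest.raises(ValueError, match="expected 2"):
            readout_predict([np.ones(2)], state)


class TestFullForward:
    def test_inference_is_deterministic(self, rng):
        cfg = ModelConfig(input_dim=8, dropout_rate=0.2, hidden_dim=6,
                          dtype="float64")
        model = GinClassifier(cfg, seed=3)
        adj = random_adjacency(rng, 8)
        l1, _, _ = model.forward(adj, training=False)
        l2, _, _ = model.forward(adj, training=False)
        np.testing.assert_array_equal(l1, l2)

    def test_permutation_invariance_of_logits(self, rng):
        """Relabeling nodes (adjacency and one-hot feature rows together)
        leaves graph-level logits unchanged — the WL-consistency property."""
        n = 30
        cfg = ModelConfig(input_dim=n, hidden_dim=8, dtype="float64")
        model = GinClassifier(cfg, seed=4)
        adj = random_adjacency(rng, n, signed=True)
        base, gates, _ = model.forward(adj)
        for _ in range(5):
            perm = rng.permutation(n)
            lp, gp, _ = model.forward(adj[np.ix_(perm, perm)],
                                      node_features=np.eye(n)[perm])
            np.testing.assert_allclose(lp, base, atol=1e-9)
            # gates are equivariant: permuted rows of the original gates
            for g0, g1 in zip(gates, gp):
                np.testing.assert_allclose(g1[0], g0[0][perm], atol=1e-9)

    def test_matches_independent_dense_oracle(self, rng):
        """Forward pass equals a from-scratch dense ((1+eps)I + A) H oracle."""
        for trial in range(10):
            n = int(rng.integers(2, 7))
            cfg = ModelConfig(input_dim=n, n_layers=2, hidden_dim=4,
                              dropout_rate=0.0, batch_norm=False,
                              epsilon_mode="learnable", epsilon_init=0.3,
                              dtype="float64")
            model = GinClassifier(cfg, seed=trial)
            p = model.state.params
            adj = random_adjacency(rng, n, density=0.7, signed=True)
            logits, gates, _ = model.forward(adj)

            h = np.eye(n)
            expected = np.zeros(2)
            for k in range(2):
                s_mat = (1 + 0.3) * np.eye(n) + adj
                z = s_mat @ h
                z = np.maximum(z @ p[f"gin{k}.lin0.W"] + p[f"gin{k}.lin0.b"], 0)
                x = np.maximum(z @ p[f"gin{k}.lin1.W"] + p[f"gin{k}.lin1.b"], 0)
                f = x @ p[f"gate{k}.W"] + p[f"gate{k}.b"]
                e = np.exp(f - f.max(axis=0))
                sm = e / e.sum(axis=0)
                g = (sm * x).sum(axis=0)
                np.testing.assert_allclose(gates[k][0], sm, atol=1e-5)
                expected += g @ p[f"read{k}.W"] + p[f"read{k}.b"]
                h = x
            np.testing.assert_allclose(logits[0], expected, atol=1e-5)

    def test_edges_change_logits(self, rng):
        n = 6
        cfg = ModelConfig(input_dim=n, hidden_dim=4, dtype="float64")
        model = GinClassifier(cfg, seed=5)
        empty, _, _ = model.forward(np.zeros((n, n)))
        complete = 0.5 * (np.ones((n, n)) - np.eye(n))
        full, _, _ = model.forward(complete)
        assert np.abs(empty - full).max() > 1e-6

    def test_gin0_equals_gin_eps_frozen_at_zero(self, rng):
        n = 7
        adj = random_adjacency(rng, n)
        m0 = GinClassifier(ModelConfig(input_dim=n, hidden_dim=4,
                                       dtype="float64"), seed=6)
        me = GinClassifier(ModelConfig(input_dim=n, hidden_dim=4,
                                       epsilon_mode="learnable",
                                       epsilon_init=0.0, dtype="float64"),
                           seed=6)
        l0, _, _ = m0.forward(adj)
        le, _, _ = me.forward(adj)
        np.testing.assert_allclose(l0, le, atol=1e-12)

    def test_node_count_mismatch_rejected(self, rng):
        model = GinClassifier(ModelConfig(input_dim=5, hidden_dim=4), seed=0)
        with pytest.raises(ValueError, match="input_dim"):
            model.forward(np.zeros((4, 4)))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Hand-coded reverse pass vs central differences, all parameters."""
        cfg = ModelConfig(input_dim=5, n_layers=2, hidden_dim=4,
                          dropout_rate=0.0, epsilon_mode="learnable",
                          dtype="float64")
        model = GinClassifier(cfg, seed=1)
        # nudge biases off zero so no ReLU sits exactly at its kink
        for key, p in model.state.params.items():
            if key.endswith(".b") or key.endswith(".beta"):
                p += rng.standard_normal(p.shape) * 0.3
        adj = np.stack([random_adjacency(rng, 5, signed=True)
                        for _ in range(3)])
        y = np.array([0, 1, 1])
        _, grads = model.loss_and_grad(adj, y, training=True)
        eps = 1e-6
        for key, p in model.state.params.items():
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = p[ix]
                bufs = {k: v.copy() for k, v in model.state.buffers.items()}
                p[ix] = orig + eps
                l1, _ = model.loss_and_grad(adj, y, training=True)
                model.state.buffers.update(bufs)
                p[ix] = orig - eps
                l2, _ = model.loss_and_grad(adj, y, training=True)
                model.state.buffers.update(bufs)
                p[ix] = orig
                num = (l1 - l2) / (2 * eps)
                assert grads[key][ix] == pytest.approx(num, abs=5e-7), key


class TestSerialization:
    def test_checkpoint_round_trip_is_bit_exact(self, rng, tmp_path):
        cfg = ModelConfig(input_dim=6, hidden_dim=5, dtype="float64")
        model = GinClassifier(cfg, seed=7)
        adj = random_adjacency(rng, 6)
        before, _, _ = model.forward(adj)
        path = tmp_path / "model.npz"
        save_state(model.state, path)
        restored = GinClassifier.load(path)
        after, _, _ = restored.forward(adj)
        np.testing.assert_array_equal(before, after)
        assert restored.config == cfg

    def test_unknown_schema_rejected(self, tmp_path):
        cfg = ModelConfig(input_dim=3, hidden_dim=2)
        state = init_state(cfg, seed=0)
        path = tmp_path / "m.npz"
        save_state(state, path)
        import json

        import numpy as np  # noqa: F811
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(bytes(arrays["__meta__"]).decode())
        meta["schema_version"] = "99"
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="schema"):
            load_state(path)
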