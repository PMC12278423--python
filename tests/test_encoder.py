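"""CGSE encoder: typed initialization, attention, propagation, gating,
contextual fusion and the counterfactual simulation operator."""

import numpy as np
import pytest

from cardiograph import autodiff as ad
from cardiograph.autodiff import Tensor
from cardiograph.domain import build_graph
from cardiograph.encoder import (EncoderParams, aggregate_layers,
                                 attention_coefficients, contextual_fusion,
                                 encode, gate_coefficient, init_node_embeddings,
                                 propagate_layer, simulate_intervention)

from conftest import random_trajectory


def set_mlp(mlp, W1, b1, W2, b2):
    mlp[0] = (Tensor(W1), Tensor(b1))
    mlp[1] = (Tensor(W2), Tensor(b2))


def passthrough_mlp(mlp, d_in, D):
    """Make an MLP behave as x -> [x, 0...] exactly (identity into R^D)."""
    big = 1e4
    W1 = np.zeros((D, d_in))
    W1[:d_in, :d_in] = np.eye(d_in) / big
    W2 = np.zeros((D, D))
    W2[:d_in, :d_in] = np.eye(d_in) * big   # tanh(x/big)*big ~ x
    set_mlp(mlp, W1, np.zeros(D), W2, np.zeros(D))


class TestInit:
    def test_identical_inputs_give_identical_embeddings(self, enc_params):
        rng = np.random.default_rng(0)
        traj = random_trajectory(rng, n_states=3)
        traj.states[1] = traj.states[0]
        g = build_graph(traj, window=5.0)
        st = init_node_embeddings(g, traj, enc_params)
        rows = [i for i, n in enumerate(g.nodes) if n.kind == "state"]
        h = st.per_layer[0].data
        np.testing.assert_array_equal(h[rows[0]], h[rows[1]])

    def test_type_dispatch_uses_kind_specific_mlp(self, tiny_traj, enc_params):
        # phi_e == 0 while phi_x != 0: event rows must be exactly zero
        for i, (W, b) in enumerate(enc_params.phi_e):
            enc_params.phi_e[i] = (Tensor(np.zeros_like(W.data)),
                                   Tensor(np.zeros_like(b.data)))
        g = build_graph(tiny_traj, window=5.0)
        st = init_node_embeddings(g, tiny_traj, enc_params)
        for i, n in enumerate(g.nodes):
            if n.kind == "event":
                np.testing.assert_array_equal(st.per_layer[0].data[i], 0.0)
            elif n.kind == "state":
                assert np.abs(st.per_layer[0].data[i]).max() > 0

    def test_passthrough_mlp_recovers_input(self, tiny_traj, enc_params):
        passthrough_mlp(enc_params.phi_x, 2, 4)
        g = build_graph(tiny_traj, window=5.0)
        st = init_node_embeddings(g, tiny_traj, enc_params)
        for i, n in enumerate(g.nodes):
            if n.kind == "state":
                np.testing.assert_allclose(st.per_layer[0].data[i, :2],
                                           tiny_traj.states[n.payload_index],
                                           atol=1e-8)

    def test_dimension_mismatch_rejected(self, tiny_traj):
        bad = EncoderParams.create(d=7, d_e=2, d_a=1, D=4, L=1, seed=0)
        g = build_graph(tiny_traj, window=5.0)
        with pytest.raises(ValueError, match="dimension"):
            init_node_embeddings(g, tiny_traj, bad)


class TestAttention:
    def test_single_neighbor_weight_is_one(self, enc_params):
        rng = np.random.default_rng(1)
        traj = random_trajectory(rng, n_states=2, n_events=0, n_actions=0)
        g = build_graph(traj, window=1e-6)
        H = rng.normal(size=(2, 4))
        w = attention_coefficients(H, g, enc_params, v=g.nodes[0].node_id)
        assert len(w) == 1
        assert next(iter(w.values())) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_neighbors_split_evenly(self, enc_params):
        rng = np.random.default_rng(2)
        traj = random_trajectory(rng, n_states=3, n_events=0, n_actions=0)
        traj.timestamps = np.array([0.0, 5.0, 10.0])
        g = build_graph(traj, window=6.0)
        H = np.tile(rng.normal(size=4), (3, 1))    # identical embeddings
        w = attention_coefficients(H, g, enc_params, v=1)
        assert set(w) == {0, 2}
        assert w[0] == pytest.approx(0.5, abs=1e-12)
        assert w[2] == pytest.approx(0.5, abs=1e-12)

    def test_softmax_of_known_exponents(self):
        # engineered so exponent arguments are exactly (-0.5, -1.0)
        params = EncoderParams.create(d=1, d_e=1, d_a=1, D=1, L=1, seed=0,
                                      lambda_attn=1.0)
        params.psi_attn = Tensor(np.array([1.0, 0.0]))
        rng = np.random.default_rng(3)
        traj = random_trajectory(rng, n_states=3, d=1, n_events=0, n_actions=0)
        traj.timestamps = np.array([0.0, 0.5, 1.0])
        g = build_graph(traj, window=2.0)
        H = np.array([[1.0], [7.0], [1.0]])   # psi^T[h_u||h_v] = h_u
        w = attention_coefficients(H, g, params, v=1)
        # exponents: -1*0.5*1 and -1*0.5*1 ... node1's neighbors are 0 and 2,
        # both |dt|=0.5, h_u=1 -> equal; use v=0 instead for distinct dts
        w = attention_coefficients(H, g, params, v=0)
        # neighbors of node 0: node1 (|dt|=.5, h=7) exponent -3.5; node2 (|dt|=1, h=1) exponent -1
        expect = np.exp([-3.5, -1.0])
        expect = expect / expect.sum()
        assert w[1] == pytest.approx(expect[0], abs=1e-9)
        assert w[2] == pytest.approx(expect[1], abs=1e-9)

    def test_exact_two_point_softmax_values(self):
        z = np.exp(-0.5) / (np.exp(-0.5) + np.exp(-1.0))
        assert z == pytest.approx(0.6225, abs=5e-5)
        assert 1 - z == pytest.approx(0.3775, abs=5e-5)

    def test_weights_positive_and_normalized_random_graphs(self, enc_params):
        rng = np.random.default_rng(4)
        for _ in range(20):
            traj = random_trajectory(rng, n_states=int(rng.integers(2, 7)))
            g = build_graph(traj, window=10.0)
            H = rng.normal(size=(g.n_nodes, 4))
            for node in g.nodes:
                if not g.in_neighbors(node.node_id):
                    continue
                w = attention_coefficients(H, g, enc_params, node.node_id)
                assert all(v > 0 for v in w.values())
                assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)

    def test_isolated_node_rejected(self, enc_params):
        rng = np.random.default_rng(5)
        traj = random_trajectory(rng, n_states=2, n_events=1, n_actions=0)
        traj.events[0] = type(traj.events[0])(time=traj.events[0].time + 100,
                                              features=traj.events[0].features,
                                              label="e")
        traj.episode_duration = 200.0
        g = build_graph(traj, window=1e-6)
        lonely = [n.node_id for n in g.nodes if not g.in_neighbors(n.node_id)]
        assert lonely
        with pytest.raises(ValueError, match="no in-neighbors"):
            attention_coefficients(np.zeros((3, 4)), g, enc_params, lonely[0])


class TestPropagation:
    def test_identity_transform_single_neighbor_copies(self):
        params = EncoderParams.create(d=1, d_e=1, d_a=1, D=2, L=1, seed=0,
                                      activation="identity")
        params.W_layers[0] = Tensor(np.eye(2))
        rng = np.random.default_rng(6)
        traj = random_trajectory(rng, n_states=2, d=1, n_events=0, n_actions=0)
        g = build_graph(traj, window=1e-6)
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = propagate_layer(H, g, params, 0)
        np.testing.assert_allclose(out.data[0], H[1], atol=1e-12)
        np.testing.assert_allclose(out.data[1], H[0], atol=1e-12)

    def test_zero_inputs_stay_zero_under_tanh(self, tiny_graph, enc_params):
        out = propagate_layer(np.zeros((5, 4)), tiny_graph, enc_params, 0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_star_graph_matches_hand_computed_sum(self):
        params = EncoderParams.create(d=1, d_e=1, d_a=1, D=2, L=1, seed=1,
                                      activation="identity", lambda_attn=0.3)
        rng = np.random.default_rng(7)
        traj = random_trajectory(rng, n_states=3, d=1, n_events=0, n_actions=0)
        traj.timestamps = np.array([0.0, 1.0, 2.0])
        g = build_graph(traj, window=2.5)   # fully connected triangle
        H = rng.normal(size=(3, 2))
        W = params.W_layers[0].data
        psi = params.psi_attn.data
        out = propagate_layer(H, g, params, 0)
        for v in range(3):
            nbrs = sorted(g.in_neighbors(v))
            scores = {u: -0.3 * abs(g.nodes[v].time - g.nodes[u].time)
                      * (psi[:2] @ H[u] + psi[2:] @ H[v]) for u in nbrs}
            m = max(scores.values())
            alphas = {u: np.exp(s - m) for u, s in scores.items()}
            Z = sum(alphas.values())
            expect = sum(alphas[u] / Z * (W @ H[u]) for u in nbrs)
            np.testing.assert_allclose(out.data[v], expect, atol=1e-9)


class TestAggregationGatingFusion:
    def test_aggregate_layers(self, tiny_graph, tiny_traj, enc_params):
        st = init_node_embeddings(tiny_graph, tiny_traj, enc_params)
        h1 = Tensor(np.random.default_rng(8).normal(size=(5, 4)))
        st.per_layer.append(h1)
        np.testing.assert_allclose(aggregate_layers(st, 1).data, h1.data)
        h2 = Tensor(np.ones((5, 4)))
        st.per_layer.append(h2)
        np.testing.assert_allclose(aggregate_layers(st, 2).data,
                                   (h1.data + 1.0) / 2)
        with pytest.raises(ValueError):
            aggregate_layers(st, 0)

    def test_gate_values(self, enc_params):
        enc_params.w_g = Tensor(np.zeros(8))
        enc_params.b_g = Tensor(0.0)
        assert gate_coefficient(np.ones(4), np.ones(4), enc_params) == \
            pytest.approx(0.5, abs=1e-12)
        enc_params.b_g = Tensor(1.0)
        assert gate_coefficient(np.ones(4), np.ones(4), enc_params) == \
            pytest.approx(0.7311, abs=5e-5)
        enc_params.b_g = Tensor(30.0)   # saturation limit: gamma -> 1
        g = gate_coefficient(np.ones(4), np.ones(4), enc_params)
        assert 0.0 < g < 1.0 and g > 1 - 1e-9

    def test_fusion_without_context_is_state_embedding(self, enc_params):
        rng = np.random.default_rng(9)
        traj = random_trajectory(rng, n_states=3, n_events=0, n_actions=0)
        g = build_graph(traj, window=5.0)
        st = encode(g, traj, enc_params)
        agg_states = st.aggregated.data[st.state_rows]
        np.testing.assert_allclose(st.fused.data, agg_states, atol=1e-12)

    def test_closed_gate_removes_context(self, tiny_traj, enc_params):
        enc_params.w_g = Tensor(np.zeros(8))
        enc_params.b_g = Tensor(-1e9)
        g = build_graph(tiny_traj, window=6.0)
        st = encode(g, tiny_traj, enc_params)
        np.testing.assert_allclose(st.fused.data,
                                   st.aggregated.data[st.state_rows], atol=1e-12)

    def test_half_gate_hand_sum(self, tiny_traj, enc_params):
        enc_params.w_g = Tensor(np.zeros(8))
        enc_params.b_g = Tensor(0.0)        # gate = 0.5 everywhere
        g = build_graph(tiny_traj, window=6.0)
        st = encode(g, tiny_traj, enc_params)
        agg = st.aggregated.data
        times = g.node_times()
        for k, row in enumerate(st.state_rows):
            t = times[row]
            ctx = [i for i, n in enumerate(g.nodes)
                   if n.kind != "state" and n.time < t]
            expect = agg[row] + 0.5 * sum(agg[i] for i in ctx)
            np.testing.assert_allclose(st.fused.data[k], expect, atol=1e-10)

    def test_contextual_fusion_requires_sample_time(self, tiny_traj, enc_params):
        g = build_graph(tiny_traj, window=6.0)
        st = encode(g, tiny_traj, enc_params)
        with pytest.raises(ValueError, match="not a sample time"):
            contextual_fusion(st, g, 3.33, enc_params)


class TestSimulationOperator:
    def test_zero_amplitude_is_identity(self, enc_params):
        enc_params.eta = Tensor(0.0)
        h = np.arange(4.0)
        out = simulate_intervention(h, np.array([1.0]), 2.0, enc_params)
        np.testing.assert_array_equal(out.data, h)

    def test_bounded_by_decaying_envelope(self, enc_params):
        rng = np.random.default_rng(10)
        eta, lam = 0.5, 1.0
        enc_params.eta = Tensor(eta)
        enc_params.lambda_sim = Tensor(lam)
        h = rng.normal(size=4)
        u = rng.normal(size=1)
        for dt in [0.0, 0.5, 1.0, 5.0, 50.0]:
            out = simulate_intervention(h, u, dt, enc_params)
            assert np.abs(out.data - h).max() <= eta * np.exp(-lam * dt) + 1e-12
        out1 = simulate_intervention(h, u, 1.0, enc_params)
        assert np.abs(out1.data - h).max() <= 0.1839 + 1e-4

    def test_effect_nonincreasing_in_dt(self, enc_params):
        rng = np.random.default_rng(11)
        h = rng.normal(size=4)
        u = rng.normal(size=1)
        dts = np.linspace(0, 10, 20)
        mags = [np.abs(simulate_intervention(h, u, dt, enc_params).data - h).max()
                for dt in dts]
        assert all(a >= b - 1e-12 for a, b in zip(mags[:-1], mags[1:]))

    def test_negative_dt_rejected(self, enc_params):
        with pytest.raises(ValueError):
            simulate_intervention(np.zeros(4), np.zeros(1), -0.1, enc_params)


# -- straight-line oracle -----------------------------------------------

def oracle_encoder(graph, traj, params):
    """Independent loop-based recomputation of init, propagation,
    aggregation and gated fusion (no shared code with the package)."""
    def mlp(ws, x):
        (W1, b1), (W2, b2) = [(w.data, b.data) for w, b in ws]
        return W2 @ np.tanh(W1 @ x + b1) + b2

    n = graph.n_nodes
    D = params.D
    h = np.zeros((n, D))
    for i, node in enumerate(graph.nodes):
        if node.kind == "state":
            h[i] = mlp(params.phi_x, traj.states[node.payload_index])
        elif node.kind == "event":
            h[i] = mlp(params.phi_e, traj.events[node.payload_index].features)
        else:
            h[i] = mlp(params.phi_a, traj.actions[node.payload_index].features)
    layers = [h]
    psi = params.psi_attn.data
    for l in range(params.L):
        W = params.W_layers[l].data
        prev = layers[-1]
        nxt = prev.copy()
        for v in range(n):
            nbrs = [e.src for e in graph.edges if e.dst == v]
            if not nbrs:
                continue
            scores = []
            for u in nbrs:
                dt = abs(graph.nodes[v].time - graph.nodes[u].time)
                sim = psi[:D] @ prev[u] + psi[D:] @ prev[v]
                scores.append(-params.lambda_attn * dt * sim)
            scores = np.array(scores)
            alpha = np.exp(scores - scores.max())
            alpha /= alpha.sum()
            nxt[v] = np.tanh(sum(a * (W @ prev[u]) for a, u in zip(alpha, nbrs)))
        layers.append(nxt)
    agg = sum(layers[1:]) / params.L
    state_rows = [i for i, nd in enumerate(graph.nodes) if nd.kind == "state"]
    fused = []
    for row in state_rows:
        t = graph.nodes[row].time
        acc = agg[row].copy()
        for j, nd in enumerate(graph.nodes):
            if nd.kind != "state" and nd.time < t:
                z = params.w_g.data @ np.concatenate([agg[j], agg[row]]) \
                    + float(params.b_g.data)
                acc += (1 / (1 + np.exp(-z))) * agg[j]
        fused.append(acc)
    return np.array(fused)


def test_full_encoder_matches_straight_line_oracle():
    rng = np.random.default_rng(12)
    for _ in range(10):
        traj = random_trajectory(rng, n_states=3, n_events=1, n_actions=1)
        params = EncoderParams.create(d=2, d_e=2, d_a=1, D=4, L=2,
                                      seed=int(rng.integers(1 << 30)))
        g = build_graph(traj, window=8.0)
        st = encode(g, traj, params)
        np.testing.assert_allclose(st.fused.data, oracle_encoder(g, traj, params),
                                   atol=1e-6)


def test_whole_encoder_bitwise_deterministic(tiny_traj, enc_params):
    g = build_graph(tiny_traj, window=6.0)
    a = encode(g, tiny_traj, enc_params)
    b = encode(g, tiny_traj, enc_params)
    for la, lb in zip(a.per_layer, b.per_layer):
        assert np.array_equal(la.data, lb.data)
    assert np.array_equal(a.fused.data, b.fused.data)
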