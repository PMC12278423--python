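"""CardioGraph Synaptic Encoder (CGSE).

Typed node initialization (one MLP per node kind), time-weighted attention
message passing over the cardiovascular graph, cross-layer aggregation,
sigmoid-gated contextual fusion of preceding events/actions into each state
embedding, and the counterfactual intervention simulation operator

    S(h, u, dt) = h + eta * exp(-lambda_sim * dt) * tanh(W_s [h || u] + b_s),

whose additive effect has amplitude ``eta`` and decays with the time
elapsed since the intervention.

All computations run on the package's autodiff tensors, so the same code
path serves inference, gradient training and finite-difference checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .domain import CardioGraph, PatientTrajectory

__all__ = [
    "EncoderParams", "EncoderState", "init_node_embeddings",
    "attention_coefficients", "propagate_layer", "aggregate_layers",
    "gate_coefficient", "contextual_fusion", "fused_sequence",
    "simulate_intervention", "encode",
]

_ACTIVATIONS = {"tanh": ad.tanh, "relu": ad.relu, "identity": lambda x: x}


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_out, fan_in)), requires_grad=True)


def make_mlp(rng: np.random.Generator, d_in: int, d_out: int,
             hidden: int | None = None) -> list[tuple[Tensor, Tensor]]:
    """Two-layer MLP parameters (tanh hidden activation, linear output)."""
    hidden = d_out if hidden is None else hidden
    return [
        (_xavier(rng, hidden, d_in), Tensor(np.zeros(hidden), requires_grad=True)),
        (_xavier(rng, d_out, hidden), Tensor(np.zeros(d_out), requires_grad=True)),
    ]


def mlp_forward(params: list[tuple[Tensor, Tensor]], x) -> Tensor:
    """Apply an MLP to rows of x (n, d_in); tanh between layers, linear last."""
    h = ad.as_tensor(x)
    for i, (W, b) in enumerate(params):
        h = ad.matmul(h, ad.transpose(W)) + b
        if i < len(params) - 1:
            h = ad.tanh(h)
    return h


@dataclass
class EncoderParams:
    """All CGSE parameters; arrays are autodiff tensors (learnable leaves)."""

    D: int
    d: int
    d_e: int
    d_a: int
    L: int
    phi_x: list = field(repr=False, default=None)
    phi_e: list = field(repr=False, default=None)
    phi_a: list = field(repr=False, default=None)
    W_layers: list = field(repr=False, default=None)
    psi_attn: Tensor = field(repr=False, default=None)
    lambda_attn: float = 0.1
    w_g: Tensor = field(repr=False, default=None)
    b_g: Tensor = field(repr=False, default=None)
    W_s: Tensor = field(repr=False, default=None)
    b_s: Tensor = field(repr=False, default=None)
    eta: Tensor = field(repr=False, default=None)
    lambda_sim: Tensor = field(repr=False, default=None)
    activation: str = "tanh"
    clamp_similarity: bool = False    # optional: clamp psi^T[.||.] to >= 0 in attention

    @classmethod
    def create(cls, d: int, d_e: int, d_a: int, D: int, L: int, seed: int,
               lambda_attn: float = 0.1, eta: float = 0.5, lambda_sim: float = 0.5,
               activation: str = "tanh", clamp_similarity: bool = False) -> "EncoderParams":
        if lambda_attn < 0 or lambda_sim < 0:
            raise ValueError("decay rates must be nonnegative")
        rng = np.random.default_rng(seed)
        return cls(
            D=D, d=d, d_e=d_e, d_a=d_a, L=L,
            phi_x=make_mlp(rng, d, D),
            phi_e=make_mlp(rng, d_e, D),
            phi_a=make_mlp(rng, d_a, D),
            W_layers=[_xavier(rng, D, D) for _ in range(L)],
            psi_attn=Tensor(rng.uniform(-0.1, 0.1, size=2 * D), requires_grad=True),
            lambda_attn=float(lambda_attn),
            w_g=Tensor(rng.uniform(-0.1, 0.1, size=2 * D), requires_grad=True),
            b_g=Tensor(0.0, requires_grad=True),
            W_s=_xavier(rng, D, D + d_a),
            b_s=Tensor(np.zeros(D), requires_grad=True),
            eta=Tensor(float(eta), requires_grad=True),
            lambda_sim=Tensor(float(lambda_sim), requires_grad=True),
            activation=activation,
            clamp_similarity=clamp_similarity,
        )


@dataclass
class EncoderState:
    """Per-layer node embeddings plus aggregated and fused representations."""

    per_layer: list            # Tensors (n_nodes, D), index 0..L
    aggregated: Tensor | None = None      # (n_nodes, D)
    fused: Tensor | None = None           # (n_steps, D), indexed like T_p
    state_rows: np.ndarray | None = None  # graph row of each state node, time order


# -- graph index cache --------------------------------------------------

def _graph_cache(graph: CardioGraph):
    src, dst = graph.edge_arrays()
    times = graph.node_times()
    has_in = np.zeros(graph.n_nodes, dtype=bool)
    has_in[dst] = True
    return src, dst, np.abs(times[dst] - times[src]), has_in


def init_node_embeddings(graph: CardioGraph, trajectory: PatientTrajectory,
                         params: EncoderParams) -> EncoderState:
    """Layer-0 embeddings: phi_x / phi_e / phi_a applied per node kind."""
    if trajectory.d != params.d:
        raise ValueError(f"state dimension {trajectory.d} != encoder d={params.d}")
    if trajectory.events and trajectory.events[0].features.shape[0] != params.d_e:
        raise ValueError("event feature dimension mismatch")
    if trajectory.actions and trajectory.actions[0].features.shape[0] != params.d_a:
        raise ValueError("action feature dimension mismatch")

    rows = {"state": [], "event": [], "action": []}
    for i, n in enumerate(graph.nodes):
        rows[n.kind].append((i, n.payload_index))

    def block(kind, mlp, payload_matrix, d_in):
        idx = rows[kind]
        feats = (payload_matrix[[p for _, p in idx]] if idx
                 else np.zeros((0, d_in)))
        return [i for i, _ in idx], mlp_forward(mlp, feats)

    ev_feats = (np.stack([e.features for e in trajectory.events])
                if trajectory.events else np.zeros((0, params.d_e)))
    ac_feats = (np.stack([a.features for a in trajectory.actions])
                if trajectory.actions else np.zeros((0, params.d_a)))

    pos_x, Hx = block("state", params.phi_x, trajectory.states, params.d)
    pos_e, He = block("event", params.phi_e, ev_feats, params.d_e)
    pos_a, Ha = block("action", params.phi_a, ac_feats, params.d_a)

    order = np.argsort(np.array(pos_x + pos_e + pos_a, dtype=np.intp))
    H0 = ad.getitem(ad.concat([Hx, He, Ha], axis=0), order)

    state_rows = np.array(pos_x, dtype=np.intp)
    return EncoderState(per_layer=[H0], state_rows=state_rows)


def _edge_attention(H: Tensor, graph: CardioGraph, params: EncoderParams,
                    cache=None) -> Tensor:
    """Softmax attention weight per directed edge, normalized over each
    destination node's in-neighborhood."""
    src, dst, absdt, _ = cache if cache is not None else _graph_cache(graph)
    D = params.D
    sim = ad.matmul(H[src], params.psi_attn[:D]) + ad.matmul(H[dst], params.psi_attn[D:])
    if params.clamp_similarity:
        sim = ad.relu(sim)
    score = sim * (-params.lambda_attn * absdt)
    # per-destination max shift: softmax-invariant, keeps exp bounded
    shift = np.full(graph.n_nodes, -np.inf)
    np.maximum.at(shift, dst, score.data)
    ex = ad.exp(score - shift[dst])
    denom = ad.segment_sum(ex, dst, graph.n_nodes)
    return ex / denom[dst]


def attention_coefficients(layer, graph: CardioGraph, params: EncoderParams,
                           v: int) -> dict[int, float]:
    """Attention weights over the in-neighborhood of node ``v``.

    ``layer`` is the (n_nodes, D) embedding matrix at the current layer
    (array, tensor, or node_id -> vector mapping).
    """
    if isinstance(layer, dict):
        H = np.stack([layer[n.node_id] for n in graph.nodes])
    else:
        H = layer
    H = ad.as_tensor(H)
    src, dst, _, _ = _graph_cache(graph)
    mask = dst == graph.node_index[v]
    if not mask.any():
        raise ValueError(f"node {v} has no in-neighbors; attention undefined")
    alpha = _edge_attention(H, graph, params).data
    return {graph.nodes[s].node_id: float(a)
            for s, a in zip(src[mask], alpha[mask])}


def propagate_layer(H, graph: CardioGraph, params: EncoderParams, l: int,
                    cache=None) -> Tensor:
    """One message-passing layer: h_v <- act(sum_u alpha_uv W^(l) h_u).

    Nodes without in-neighbors keep their previous embedding.
    """
    if not 0 <= l < params.L:
        raise ValueError(f"layer index {l} outside 0..{params.L - 1}")
    H = ad.as_tensor(H)
    cache = cache if cache is not None else _graph_cache(graph)
    src, dst, _, has_in = cache
    alpha = _edge_attention(H, graph, params, cache)
    msg = ad.matmul(H[src], ad.transpose(params.W_layers[l]))
    msg = msg * ad.reshape(alpha, (-1, 1))
    agg = ad.segment_sum(msg, dst, graph.n_nodes)
    out = _ACTIVATIONS[params.activation](agg)
    keep = (~has_in).astype(np.float64).reshape(-1, 1)
    return out * has_in.astype(np.float64).reshape(-1, 1) + H * keep


def aggregate_layers(state: EncoderState, L: int) -> Tensor:
    """Cross-layer aggregation: mean of layers 1..L."""
    if L <= 0:
        raise ValueError("L must be >= 1")
    if len(state.per_layer) < L + 1:
        raise ValueError(f"only {len(state.per_layer) - 1} layers computed, need {L}")
    acc = state.per_layer[1]
    for l in range(2, L + 1):
        acc = acc + state.per_layer[l]
    return acc * (1.0 / L)


def gate_coefficient(h_v_agg, h_x_agg, params: EncoderParams):
    """Sigmoid gate on the concatenated aggregated embeddings, in (0, 1)."""
    h_v = ad.as_tensor(h_v_agg)
    h_x = ad.as_tensor(h_x_agg)
    z = ad.matmul(ad.concat([h_v, h_x]), params.w_g) + params.b_g
    g = ad.sigmoid(z)
    if isinstance(h_v_agg, Tensor) or isinstance(h_x_agg, Tensor):
        return g
    return float(g.data)


def fused_sequence(aggregated, graph: CardioGraph, params: EncoderParams,
                   state_rows: np.ndarray) -> Tensor:
    """Fused per-time-step embeddings: state embedding plus gated sum of all
    strictly preceding event/action embeddings."""
    H = ad.as_tensor(aggregated)
    state_times = graph.node_times()[state_rows]
    ctx_rows = np.array([i for i, n in enumerate(graph.nodes)
                         if n.kind != "state"], dtype=np.intp)
    base = H[state_rows]
    if ctx_rows.size == 0:
        return base
    ctx_times = graph.node_times()[ctx_rows]
    pair_ctx, pair_t = [], []
    for c, tc in zip(ctx_rows, ctx_times):
        j = int(np.searchsorted(state_times, tc, side="right"))
        for i in range(j, len(state_rows)):
            pair_ctx.append(c)
            pair_t.append(i)
    if not pair_ctx:
        return base
    pair_ctx = np.array(pair_ctx, dtype=np.intp)
    pair_t = np.array(pair_t, dtype=np.intp)
    hv = H[pair_ctx]
    hx = H[state_rows[pair_t]]
    z = ad.matmul(ad.concat([hv, hx], axis=1), params.w_g) + params.b_g
    gamma = ad.sigmoid(z)
    contrib = hv * ad.reshape(gamma, (-1, 1))
    return base + ad.segment_sum(contrib, pair_t, len(state_rows))


def contextual_fusion(state: EncoderState, graph: CardioGraph, t: float,
                      params: EncoderParams):
    """Fused embedding at one sample time t in T_p."""
    if state.aggregated is None:
        raise ValueError("aggregated embeddings not computed")
    state_times = graph.node_times()[state.state_rows]
    hits = np.where(np.isclose(state_times, t))[0]
    if hits.size == 0:
        raise ValueError(f"t={t} is not a sample time of this trajectory")
    fused = fused_sequence(state.aggregated, graph, params, state.state_rows)
    return fused[int(hits[0])]


def simulate_intervention(h, u, dt, params: EncoderParams):
    """Counterfactual simulation operator S(h, u, dt); dt >= 0 seconds.

    Accepts a single vector (D,) with u (d_a,), or batches (B, D)/(B, d_a)
    with dt scalar or (B,).
    """
    dt_arr = np.asarray(dt, dtype=np.float64)
    if np.any(dt_arr < 0):
        raise ValueError("dt must be >= 0")
    h = ad.as_tensor(h)
    u = ad.as_tensor(u)
    axis = h.data.ndim - 1
    pre = ad.matmul(ad.concat([h, u], axis=axis), ad.transpose(params.W_s)) + params.b_s
    decay = ad.exp(params.lambda_sim * Tensor(-dt_arr))
    if h.data.ndim == 2:
        decay = ad.reshape(decay, (-1, 1)) if dt_arr.ndim == 1 else decay
    return h + params.eta * decay * ad.tanh(pre)


def encode(graph: CardioGraph, trajectory: PatientTrajectory,
           params: EncoderParams) -> EncoderState:
    """Full CGSE pass: init, L propagation layers, aggregation, fusion."""
    state = init_node_embeddings(graph, trajectory, params)
    cache = _graph_cache(graph)
    for l in range(params.L):
        state.per_layer.append(
            propagate_layer(state.per_layer[-1], graph, params, l, cache))
    state.aggregated = aggregate_layers(state, params.L)
    state.fused = fused_sequence(state.aggregated, graph, params, state.state_rows)
    return state
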