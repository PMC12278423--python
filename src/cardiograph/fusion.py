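"""Trajectory-level pooling, bidirectional recurrent context, bi-temporal
fusion, and the latent-geometry constraint.

The fused per-step embeddings from the encoder are summarized two ways:
a temporal attention pool yields one trajectory vector H_p, and a pair of
GRUs scanned forward and backward yield per-step context vectors that are
fused and added back to give the final state representation s_t.  A soft
hinge penalty ties latent distances ||s_{t1} - s_{t2}|| to the observed
physiological path length between the same times, keeping the latent
geometry faithful to measured dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .domain import PatientTrajectory

__all__ = [
    "FusionParams", "FusedTrajectory", "attention_pool", "gru_cell",
    "bidirectional_context", "bidirectional_context_batch", "fuse_bitemporal",
    "final_state", "latent_distance", "observed_change", "geometry_penalty",
    "consistency_pairs", "fuse_trajectory",
]


def _gru_params(rng: np.random.Generator, D: int) -> dict[str, Tensor]:
    def mat():
        limit = np.sqrt(6.0 / (2 * D))
        return Tensor(rng.uniform(-limit, limit, size=(D, D)), requires_grad=True)

    out = {}
    for gate in ("z", "r", "n"):
        out[f"W_{gate}"] = mat()
        out[f"U_{gate}"] = mat()
        out[f"b_{gate}"] = Tensor(np.zeros(D), requires_grad=True)
    return out


@dataclass
class FusionParams:
    D: int
    q: Tensor = field(repr=False, default=None)
    W_q: Tensor = field(repr=False, default=None)
    gru_fwd: dict = field(repr=False, default=None)
    gru_bwd: dict = field(repr=False, default=None)
    W_f: Tensor = field(repr=False, default=None)
    b_f: Tensor = field(repr=False, default=None)
    epsilon_geom: float = 0.1
    obs_scale: Tensor = field(repr=False, default=None)  # multiplies observed change

    @classmethod
    def create(cls, D: int, seed: int, epsilon_geom: float = 0.1,
               learn_obs_scale: bool = False) -> "FusionParams":
        if epsilon_geom < 0:
            raise ValueError("epsilon_geom must be >= 0")
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (3 * D))
        return cls(
            D=D,
            q=Tensor(rng.uniform(-0.5, 0.5, size=D), requires_grad=True),
            W_q=Tensor(rng.uniform(-limit, limit, size=(D, D)), requires_grad=True),
            gru_fwd=_gru_params(rng, D),
            gru_bwd=_gru_params(rng, D),
            W_f=Tensor(rng.uniform(-limit, limit, size=(D, 2 * D)), requires_grad=True),
            b_f=Tensor(np.zeros(D), requires_grad=True),
            epsilon_geom=float(epsilon_geom),
            obs_scale=Tensor(1.0, requires_grad=learn_obs_scale),
        )


@dataclass
class FusedTrajectory:
    """All per-trajectory fusion outputs, indexed like the sample times."""

    H_p: Tensor                 # (D,)
    pool_weights: Tensor        # (T,)
    r: Tensor                   # (T, D) forward contexts
    b: Tensor                   # (T, D) backward contexts
    c: Tensor                   # (T, D) fused contexts
    s: Tensor                   # (T, D) final states


def _maybe_unwrap(out, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    if isinstance(out, tuple):
        return tuple(o.data if isinstance(o, Tensor) else o for o in out)
    return out.data if isinstance(out, Tensor) else out


def attention_pool(h_tilde_seq, params: FusionParams):
    """Temporal attention pooling: softmax(q^T tanh(W_q h_t)) weights."""
    H = ad.as_tensor(h_tilde_seq)
    if H.data.ndim != 2 or H.data.shape[0] == 0:
        raise ValueError("attention_pool needs a non-empty (T, D) sequence")
    scores = ad.matmul(ad.tanh(ad.matmul(H, ad.transpose(params.W_q))), params.q)
    shift = float(scores.data.max())
    ex = ad.exp(scores - shift)
    weights = ex / ad.tsum(ex)
    H_p = ad.matmul(weights, H)
    return _maybe_unwrap((H_p, weights), h_tilde_seq)


def gru_cell(params: dict, x, h):
    """Standard GRU cell: update z, reset r, candidate n; rows are a batch."""
    x = ad.as_tensor(x)
    h = ad.as_tensor(h)
    z = ad.sigmoid(ad.matmul(x, ad.transpose(params["W_z"]))
                   + ad.matmul(h, ad.transpose(params["U_z"])) + params["b_z"])
    r = ad.sigmoid(ad.matmul(x, ad.transpose(params["W_r"]))
                   + ad.matmul(h, ad.transpose(params["U_r"])) + params["b_r"])
    n = ad.tanh(ad.matmul(x, ad.transpose(params["W_n"]))
                + ad.matmul(r * h, ad.transpose(params["U_n"])) + params["b_n"])
    return (1.0 - z) * n + z * h


def bidirectional_context_batch(H, params: FusionParams) -> tuple[Tensor, Tensor]:
    """Forward and backward GRU scans over a (B, T, D) batch, zero-initialized."""
    H = ad.as_tensor(H)
    B, T, D = H.data.shape
    fwd, bwd = [], []
    h = Tensor(np.zeros((B, D)))
    for t in range(T):
        h = gru_cell(params.gru_fwd, H[:, t, :], h)
        fwd.append(h)
    h = Tensor(np.zeros((B, D)))
    for t in range(T - 1, -1, -1):
        h = gru_cell(params.gru_bwd, H[:, t, :], h)
        bwd.append(h)
    bwd.reverse()
    return ad.stack(fwd, axis=1), ad.stack(bwd, axis=1)


def bidirectional_context(h_tilde_seq, params: FusionParams):
    """Forward contexts r_t and backward contexts b_t for one (T, D) sequence."""
    H = ad.as_tensor(h_tilde_seq)
    if H.data.ndim != 2 or H.data.shape[0] == 0:
        raise ValueError("bidirectional_context needs a non-empty (T, D) sequence")
    r3, b3 = bidirectional_context_batch(ad.reshape(H, (1,) + H.data.shape), params)
    r = ad.reshape(r3, H.data.shape)
    b = ad.reshape(b3, H.data.shape)
    return _maybe_unwrap((r, b), h_tilde_seq)


def fuse_bitemporal(r_t, b_t, params: FusionParams):
    """c_t = W_f [r_t || b_t] + b_f (single vectors or (T, D) sequences)."""
    r = ad.as_tensor(r_t)
    b = ad.as_tensor(b_t)
    axis = r.data.ndim - 1
    c = ad.matmul(ad.concat([r, b], axis=axis), ad.transpose(params.W_f)) + params.b_f
    return _maybe_unwrap(c, r_t, b_t)


def final_state(h_tilde_t, c_t):
    """s_t = h_tilde_t + c_t."""
    out = ad.as_tensor(h_tilde_t) + ad.as_tensor(c_t)
    return _maybe_unwrap(out, h_tilde_t, c_t)


def latent_distance(s_a, s_b):
    """Euclidean distance between two latent states."""
    d = ad.sqrt(ad.tsum((ad.as_tensor(s_a) - ad.as_tensor(s_b)) ** 2))
    if isinstance(s_a, Tensor) or isinstance(s_b, Tensor):
        return d
    return float(d.data)


def observed_change(trajectory: PatientTrajectory, t1: float, t2: float) -> float:
    """Discrete path length of the observed states over [t1, t2].

    Piecewise-linear quadrature of the integral of ||dx/dt||: the sum of
    ||x_{i+1} - x_i|| over consecutive samples inside the window.  Both
    endpoints must be sample times.
    """
    if t1 >= t2:
        raise ValueError("observed_change requires t1 < t2")
    ts = trajectory.timestamps
    for t in (t1, t2):
        if not np.any(np.isclose(ts, t)):
            raise ValueError(f"t={t} is not a sample time of this trajectory")
    mask = (ts >= t1 - 1e-12) & (ts <= t2 + 1e-12)
    X = trajectory.states[mask]
    if len(X) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(X, axis=0), axis=1).sum())


def geometry_penalty(s_seq, trajectory: PatientTrajectory, params: FusionParams,
                     pairs: list[tuple[float, float]]):
    """Soft relaxation of the latent-geometry constraint.

    For each pair of sample times, penalize the excess of
    |d_lat(t1,t2) - scale * Delta_obs(t1,t2)| over the tolerance epsilon,
    squared.  Zero exactly when every pair satisfies the constraint.
    """
    S = ad.as_tensor(s_seq)
    ts = trajectory.timestamps
    if not pairs:
        return 0.0 if not isinstance(s_seq, Tensor) else Tensor(0.0)
    # cumulative path length makes every pair's observed change O(1)
    seg = np.linalg.norm(np.diff(trajectory.states, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    i1 = np.array([int(np.argmin(np.abs(ts - t1))) for t1, _ in pairs], dtype=np.intp)
    i2 = np.array([int(np.argmin(np.abs(ts - t2))) for _, t2 in pairs], dtype=np.intp)
    deltas = np.abs(cum[i2] - cum[i1])
    d_lat = ad.sqrt(ad.tsum((S[i1] - S[i2]) ** 2, axis=1) + 1e-300)
    gap = ad.relu(ad.absolute(d_lat - params.obs_scale * deltas) - params.epsilon_geom)
    total = ad.tsum(gap ** 2)
    if isinstance(s_seq, Tensor):
        return total
    return float(total.data)


def consistency_pairs(timestamps: np.ndarray, n_random: int,
                      rng: np.random.Generator) -> list[tuple[float, float]]:
    """Geometry-constraint pairs: all consecutive pairs plus seeded random
    non-adjacent pairs."""
    ts = np.asarray(timestamps, dtype=np.float64)
    pairs = [(float(a), float(b)) for a, b in zip(ts[:-1], ts[1:])]
    n = len(ts)
    if n > 2:
        for _ in range(n_random):
            i = int(rng.integers(0, n - 2))
            j = int(rng.integers(i + 2, n))
            pairs.append((float(ts[i]), float(ts[j])))
    return pairs


def fuse_trajectory(h_tilde_seq, params: FusionParams) -> FusedTrajectory:
    """Full fusion pass for one trajectory's fused encoder sequence."""
    H = ad.as_tensor(h_tilde_seq)
    H_p, w = attention_pool(H, params)
    r, b = bidirectional_context(H, params)
    c = fuse_bitemporal(r, b, params)
    s = final_state(H, c)
    return FusedTrajectory(H_p=H_p, pool_weights=w, r=r, b=b, c=c, s=s)
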