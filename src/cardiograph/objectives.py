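"""Trajectory-alignment objectives and structural regularizers (DCTA).

Every loss is a plain function of latent state sequences (and, where
relevant, graph structure or anchor parameters), usable on raw numpy
arrays for inspection or on autodiff tensors inside the training
objective.  Conventions:

* quadratic residual losses are sums of squared Euclidean norms;
* stage separation uses exp(-squared centroid distance), so it decays as
  phases separate; anchor separation uses the reciprocal form
  1 / (squared distance + eps);
* the graph smoothness term is the Laplacian quadratic form of the
  undirected, unit-weight support of the patient graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .domain import CardioGraph

__all__ = [
    "StageSegmentation", "EventAnchors", "PriorProjection",
    "VectorFieldRegistry", "ExponentialResponseField", "LossBundle",
    "resample_to_grid", "alignment_loss", "prior_loss", "arc_length_loss",
    "stage_statistics", "stage_separation_loss", "soft_alignment_loss",
    "nearest_index_alignment", "intervention_effect",
    "intervention_orientation_loss", "event_anchor_loss",
    "anchor_separation_loss", "laplacian_smoothness", "total_objective",
    "LOSS_NAMES",
]

LOSS_NAMES = (
    "prediction", "align", "prior", "arc", "stage_sep", "soft_align",
    "interv_orient", "event_anchor", "anchor_sep", "laplacian", "geometry",
)


def _maybe(out: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return float(out.data)


def _sqnorm(x: Tensor, axis=None) -> Tensor:
    return ad.tsum(x ** 2, axis=axis)


# -- types --------------------------------------------------------------

@dataclass
class StageSegmentation:
    """Contiguous segmentation of a latent sequence with per-stage moments."""

    K: int
    segments: list[np.ndarray]       # index arrays partitioning 0..T-1
    centroids: list                  # K tensors/arrays (D,)
    covariances: list                # K tensors/arrays (D, D)


@dataclass
class EventAnchors:
    """Latent attractor point per clinical event label."""

    centers: dict[str, Tensor]
    eps_anchor: float = 0.01

    def __post_init__(self):
        if self.eps_anchor <= 0:
            raise ValueError("eps_anchor must be > 0")

    @classmethod
    def create(cls, labels: list[str], D: int, seed: int,
               eps_anchor: float = 0.01) -> "EventAnchors":
        rng = np.random.default_rng(seed)
        centers = {lab: Tensor(rng.normal(0, 0.5, size=D), requires_grad=True)
                   for lab in sorted(labels)}
        return cls(centers=centers, eps_anchor=eps_anchor)


@dataclass
class PriorProjection:
    """Affine map from latent space to the clinical-prior feature space."""

    W: Tensor            # (d_prior, D)
    b: Tensor            # (d_prior,)

    @classmethod
    def create(cls, D: int, d_prior: int, seed: int) -> "PriorProjection":
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (D + d_prior))
        return cls(W=Tensor(rng.uniform(-limit, limit, size=(d_prior, D)),
                            requires_grad=True),
                   b=Tensor(np.zeros(d_prior), requires_grad=True))

    def __call__(self, s):
        return ad.matmul(ad.as_tensor(s), ad.transpose(self.W)) + self.b


class ExponentialResponseField:
    """Expected physiological response to an intervention: an amplitude-
    scaled direction decaying exponentially in elapsed time,
    G(u, dt) = A * ||u|| * exp(-dt / tau)."""

    def __init__(self, direction: np.ndarray, tau: float):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.direction = np.asarray(direction, dtype=np.float64)
        self.tau = float(tau)

    def __call__(self, u, dt: float) -> np.ndarray:
        u = np.asarray(u, dtype=np.float64)
        return self.direction * float(np.linalg.norm(u)) * np.exp(-dt / self.tau)


class VectorFieldRegistry:
    """Named registry of expected intervention-response vector fields."""

    def __init__(self):
        self._fields: dict[str, object] = {}

    def register(self, name: str, fld) -> None:
        self._fields[name] = fld

    def get(self, name: str):
        if name not in self._fields:
            raise ValueError(f"unknown vector field {name!r}; "
                             f"registered: {sorted(self._fields)}")
        return self._fields[name]

    def names(self) -> list[str]:
        return sorted(self._fields)


# -- alignment ----------------------------------------------------------

def resample_to_grid(s_seq, timestamps, n_grid: int = 32):
    """Linear interpolation of a latent sequence onto a normalized-time grid.

    Makes trajectories with different sampling comparable pointwise.
    Operates on plain arrays (resampling is a data-preparation step).
    """
    S = s_seq.data if isinstance(s_seq, Tensor) else np.asarray(s_seq, dtype=np.float64)
    ts = np.asarray(timestamps, dtype=np.float64)
    if len(ts) != len(S):
        raise ValueError("sequence and timestamps length mismatch")
    if len(ts) == 1:
        return np.repeat(S, n_grid, axis=0)
    tau = (ts - ts[0]) / (ts[-1] - ts[0])
    grid = np.linspace(0.0, 1.0, n_grid)
    return np.stack([np.interp(grid, tau, S[:, j]) for j in range(S.shape[1])], axis=1)


def alignment_loss(s_p, s_q):
    """Cross-patient alignment: sum_t ||s_t^(p) - s_t^(q)||^2 on a shared grid."""
    P = ad.as_tensor(s_p)
    Q = ad.as_tensor(s_q)
    if P.data.shape != Q.data.shape:
        raise ValueError(f"aligned sequences must share a grid: "
                         f"{P.data.shape} vs {Q.data.shape}")
    return _maybe(_sqnorm(P - Q), s_p, s_q)


def prior_loss(s_seq, proj: PriorProjection, p_seq):
    """Pathway-constrained evolution: sum_t ||f(s_t) - p_t||^2."""
    S = ad.as_tensor(s_seq)
    p = np.asarray(p_seq.data if isinstance(p_seq, Tensor) else p_seq, dtype=np.float64)
    return _maybe(_sqnorm(proj(S) - p), s_seq)


def arc_length_loss(s_seq, timestamps):
    """Squared-speed arc-length regularizer on the normalized-time path.

    Discretized integral of ||d gamma / d tau||^2:
    sum_i ||s_{i+1} - s_i||^2 / dtau_i, with tau the min-max normalized time.
    """
    S = ad.as_tensor(s_seq)
    ts = np.asarray(timestamps, dtype=np.float64)
    if len(ts) < 2:
        return _maybe(Tensor(0.0), s_seq)
    tau = (ts - ts[0]) / (ts[-1] - ts[0])
    dtau = np.diff(tau)
    if np.any(dtau <= 0):
        raise ValueError("timestamps must be strictly increasing")
    diff = S[1:] - S[:-1]
    per_step = ad.tsum(diff ** 2, axis=1) / dtau
    return _maybe(ad.tsum(per_step), s_seq)


def stage_statistics(s_seq, K: int) -> StageSegmentation:
    """Contiguous equal-size segmentation with per-stage centroid and
    population covariance (remainder indices go to the last segment)."""
    if K <= 0:
        raise ValueError("K must be >= 1")
    S = ad.as_tensor(s_seq)
    T = S.data.shape[0]
    if T < K:
        raise ValueError(f"sequence length {T} < K={K}")
    size = T // K
    bounds = [0] + [size * k for k in range(1, K)] + [T]
    segments, centroids, covariances = [], [], []
    for k in range(K):
        idx = np.arange(bounds[k], bounds[k + 1])
        seg = S[idx]
        mu = ad.tmean(seg, axis=0)
        dev = seg - mu
        cov = ad.matmul(ad.transpose(dev), dev) * (1.0 / len(idx))
        segments.append(idx)
        centroids.append(_maybe_arr(mu, s_seq))
        covariances.append(_maybe_arr(cov, s_seq))
    return StageSegmentation(K=K, segments=segments, centroids=centroids,
                             covariances=covariances)


def _maybe_arr(out: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return out
    return out.data


def stage_separation_loss(seg: StageSegmentation):
    """Phase-separation regularizer: sum_{i<j} exp(-||mu_i - mu_j||^2)."""
    mus = [ad.as_tensor(m) for m in seg.centroids]
    total = Tensor(0.0)
    for i in range(len(mus)):
        for j in range(i + 1, len(mus)):
            total = total + ad.exp(-_sqnorm(mus[i] - mus[j]))
    return _maybe(total, *seg.centroids)


def nearest_index_alignment(ts_p, ts_q) -> np.ndarray:
    """Monotone soft alignment pi: each normalized time of p maps to the
    nearest normalized time of q (by index)."""
    ts_p = np.asarray(ts_p, dtype=np.float64)
    ts_q = np.asarray(ts_q, dtype=np.float64)
    np_ = (ts_p - ts_p[0]) / max(ts_p[-1] - ts_p[0], 1e-300)
    nq = (ts_q - ts_q[0]) / max(ts_q[-1] - ts_q[0], 1e-300)
    return np.array([int(np.argmin(np.abs(nq - t))) for t in np_], dtype=np.intp)


def soft_alignment_loss(s_p, s_q, pi):
    """Soft temporal alignment: sum_{t} ||s_t^(p) - s_{pi(t)}^(q)||^2."""
    P = ad.as_tensor(s_p)
    Q = ad.as_tensor(s_q)
    pi = np.asarray(pi, dtype=np.intp)
    if len(pi) != P.data.shape[0]:
        raise ValueError("pi must map every time step of the source sequence")
    if np.any(np.diff(pi) < 0):
        raise ValueError("pi must be monotone non-decreasing")
    if np.any(pi < 0) or np.any(pi >= Q.data.shape[0]):
        raise ValueError("pi maps outside the target sequence")
    return _maybe(_sqnorm(P - Q[pi]), s_p, s_q)


# -- event-driven control ----------------------------------------------

def intervention_effect(s_hat_tprime, s_tprime):
    """delta = counterfactual state minus factual state."""
    out = ad.as_tensor(s_hat_tprime) - ad.as_tensor(s_tprime)
    if isinstance(s_hat_tprime, Tensor) or isinstance(s_tprime, Tensor):
        return out
    return out.data


def intervention_orientation_loss(delta, u, dt: float,
                                  registry: VectorFieldRegistry, fld: str):
    """||delta - G(u, dt)||^2 against the named expected-response field."""
    G = registry.get(fld)(u, dt)
    d = ad.as_tensor(delta)
    return _maybe(_sqnorm(d - np.asarray(G, dtype=np.float64)), delta)


def event_anchor_loss(s_at_event, anchors: EventAnchors, label: str):
    """Pull the state at an event time toward the label's attractor point."""
    if label not in anchors.centers:
        raise ValueError(f"no anchor for event label {label!r}; "
                         f"known: {sorted(anchors.centers)}")
    s = ad.as_tensor(s_at_event)
    out = _sqnorm(s - anchors.centers[label])
    if isinstance(s_at_event, Tensor) or anchors.centers[label].requires_grad:
        return out
    return float(out.data)


def anchor_separation_loss(anchors: EventAnchors):
    """Reciprocal separation of anchor centers: sum_{i<j} 1/(||ci-cj||^2 + eps)."""
    labels = sorted(anchors.centers)
    total = Tensor(0.0)
    grad = False
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ci = anchors.centers[labels[i]]
            cj = anchors.centers[labels[j]]
            grad = grad or ci.requires_grad or cj.requires_grad
            total = total + 1.0 / (_sqnorm(ci - cj) + anchors.eps_anchor)
    return total if grad else float(total.data)


def laplacian_smoothness(H, graph: CardioGraph):
    """Graph-smoothness quadratic form over the undirected unit-weight
    support: sum over undirected edges of ||h_u - h_v||^2 (equal to
    Tr(H^T L H) for the unnormalized Laplacian L)."""
    Ht = ad.as_tensor(H)
    support = sorted(graph.undirected_support())
    if not support:
        return _maybe(Tensor(0.0), H)
    us = np.array([u for u, _ in support], dtype=np.intp)
    vs = np.array([v for _, v in support], dtype=np.intp)
    return _maybe(_sqnorm(Ht[us] - Ht[vs]), H)


def total_objective(components: dict, weights: dict[str, float]):
    """Weighted total of named loss components.

    Returns a LossBundle; if any component is a tensor the bundle's
    ``total_tensor`` carries the differentiable total.
    """
    unknown = set(components) - set(LOSS_NAMES)
    if unknown:
        raise ValueError(f"unknown loss components: {sorted(unknown)}")
    for name, w in weights.items():
        if name not in LOSS_NAMES:
            raise ValueError(f"unknown loss weight {name!r}")
        if w < 0:
            raise ValueError(f"loss weight {name!r} must be >= 0")
    total = Tensor(0.0)
    values = {}
    for name, comp in components.items():
        w = float(weights.get(name, 0.0))
        ct = ad.as_tensor(comp)
        values[name] = float(ct.data)
        total = total + w * ct
    bundle = LossBundle(values=values,
                        weights={n: float(weights.get(n, 0.0)) for n in components},
                        total=float(total.data))
    bundle.total_tensor = total if total.requires_grad else None
    return bundle


@dataclass
class LossBundle:
    """Named scalar loss values, their weights, and the weighted total."""

    values: dict[str, float]
    weights: dict[str, float]
    total: float
    total_tensor: Tensor | None = field(default=None, repr=False, compare=False)

    def as_row(self) -> dict[str, float]:
        row = {f"loss_{k}": v for k, v in sorted(self.values.items())}
        row["total"] = self.total
        return row
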