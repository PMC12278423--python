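"""End-to-end training of the graph encoder + fusion + alignment objective.

One optimization step runs the full pipeline on a cohort: per-patient graph
encoding, batched bidirectional GRU fusion, a linear forecast head
supervised with MSE (or L1), and the structural alignment/regularization
terms, combined by a curriculum-scheduled weighted sum.  All randomness
(parameter init, pair sampling, intervention subsampling) derives from the
run seed, and the default single-threaded execution is exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, recall_score

from . import autodiff as ad
from . import encoder as enc_mod
from . import fusion as fus_mod
from . import objectives as obj
from .autodiff import Tensor
from .domain import CardioGraph, CausalPriorTable, PatientTrajectory, build_graph
from .synthetic import CohortGroundTruth

__all__ = [
    "RunConfig", "ForecastHead", "Model", "forecast", "curriculum_weights",
    "train", "evaluate", "lvcf_baseline", "init_model", "named_tensors",
    "save_checkpoint", "load_checkpoint", "compute_metrics",
]

_STRUCTURAL = tuple(n for n in obj.LOSS_NAMES if n != "prediction")


@dataclass
class RunConfig:
    """Everything a run needs; ``seed`` is mandatory."""

    seed: int
    d: int = 6
    d_e: int = 3
    d_a: int = 3
    D: int = 16
    L: int = 2
    K: int = 4
    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 0              # 0 = full cohort per optimizer step
    horizon: int = 1
    loss_type: str = "mse"           # "mse" | "l1"
    forecast_mode: str = "residual"  # "residual": x_t + readout(s_t); "absolute"
    graph_window: float = 10.0       # seconds, temporal co-occurrence
    lambda_attn: float = 0.1
    eta: float = 0.5
    lambda_sim: float = 0.5
    epsilon_geom: float = 0.1
    anomaly_threshold: float = 0.5   # forecast-residual norm threshold
    n_grid: int = 32                 # normalized-time grid for alignment
    n_align_pairs: int = 4
    n_geom_random_pairs: int = 4
    interventions_per_batch: int = 8
    strides: tuple[int, ...] = (1, 2, 4)
    risk_center: float | None = None     # optional Gaussian loss mask center (s)
    risk_sigma: float = 30.0
    loss_weights: dict[str, float] = field(default_factory=lambda: {
        "prediction": 1.0, **{n: 0.1 for n in _STRUCTURAL}})
    curriculum: list[tuple[int, dict[str, float]]] = field(default_factory=lambda: [
        (0, {n: 0.0 for n in _STRUCTURAL}),
        (5, {}),
    ])
    cohort_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("d", "d_e", "d_a", "D", "L", "K", "horizon"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.loss_type not in ("mse", "l1"):
            raise ValueError("loss_type must be 'mse' or 'l1'")
        if self.forecast_mode not in ("residual", "absolute"):
            raise ValueError("forecast_mode must be 'residual' or 'absolute'")
        bad = set(self.loss_weights) - set(obj.LOSS_NAMES)
        if bad:
            raise ValueError(f"unknown loss weights: {sorted(bad)}")
        self.curriculum = sorted([(int(e), dict(o)) for e, o in self.curriculum])

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ForecastHead:
    """Affine readout from latent state s_t to the state h steps ahead."""

    W: Tensor            # (d, D)
    b: Tensor            # (d,)
    horizon: int = 1

    @classmethod
    def create(cls, D: int, d: int, seed: int, horizon: int = 1,
               zero_init: bool = False) -> "ForecastHead":
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        rng = np.random.default_rng(seed)
        limit = np.sqrt(6.0 / (D + d))
        W = np.zeros((d, D)) if zero_init else rng.uniform(-limit, limit, size=(d, D))
        return cls(W=Tensor(W, requires_grad=True),
                   b=Tensor(np.zeros(d), requires_grad=True), horizon=horizon)


@dataclass
class Model:
    enc: enc_mod.EncoderParams
    fus: fus_mod.FusionParams
    head: ForecastHead
    proj: obj.PriorProjection
    anchors: obj.EventAnchors
    registry: obj.VectorFieldRegistry = field(default_factory=obj.VectorFieldRegistry)


def _latent_direction(label: str, D: int) -> np.ndarray:
    rng = np.random.default_rng(zlib.crc32(("field:" + label).encode()) % (2 ** 31))
    v = rng.normal(size=D)
    return v / np.linalg.norm(v)


def init_model(config: RunConfig, event_labels: list[str],
               action_labels: list[str]) -> Model:
    model = Model(
        enc=enc_mod.EncoderParams.create(
            d=config.d, d_e=config.d_e, d_a=config.d_a, D=config.D, L=config.L,
            seed=config.seed, lambda_attn=config.lambda_attn, eta=config.eta,
            lambda_sim=config.lambda_sim),
        fus=fus_mod.FusionParams.create(D=config.D, seed=config.seed + 1,
                                        epsilon_geom=config.epsilon_geom),
        # a residual head starts as exact persistence, so the readout is
        # zero-initialized and only learns the correction
        head=ForecastHead.create(D=config.D, d=config.d, seed=config.seed + 2,
                                 horizon=config.horizon,
                                 zero_init=(config.forecast_mode == "residual")),
        proj=obj.PriorProjection.create(D=config.D, d_prior=config.d,
                                        seed=config.seed + 3),
        anchors=obj.EventAnchors.create(labels=event_labels or ["event"],
                                        D=config.D, seed=config.seed + 4),
    )
    # expected-response field per intervention label: fixed unit direction in
    # latent space with a 2 s decay constant (a structural prior, not learned)
    for lab in action_labels or ["action"]:
        model.registry.register(
            lab, obj.ExponentialResponseField(_latent_direction(lab, config.D), tau=2.0))
    return model


def forecast(fused: fus_mod.FusedTrajectory, head: ForecastHead):
    """Per-step forecasts: row t predicts the state ``horizon`` steps ahead."""
    s = ad.as_tensor(fused.s)
    out = ad.matmul(s, ad.transpose(head.W)) + head.b
    return out if s.requires_grad else out.data


def curriculum_weights(epoch: int, config: RunConfig) -> dict[str, float]:
    """Piecewise-constant schedule: the last entry with start <= epoch applies
    on top of the base weights (closed left endpoint)."""
    weights = dict(config.loss_weights)
    active: dict[str, float] = {}
    for start, overrides in config.curriculum:
        if start <= epoch:
            active = overrides
    weights.update(active)
    return weights


def lvcf_baseline(cohort: list[PatientTrajectory], horizon: int = 1) -> float:
    """Last-value-carried-forward forecast MSE (persistence baseline)."""
    errs = []
    for traj in cohort:
        X = traj.states
        errs.append(((X[horizon:] - X[:-horizon]) ** 2).ravel())
    return float(np.mean(np.concatenate(errs)))


# -- internals ----------------------------------------------------------

def _interp_matrix(ts: np.ndarray, n_grid: int) -> np.ndarray:
    """Constant (n_grid, T) matrix performing linear interpolation onto the
    normalized-time grid; multiplying latent sequences by it keeps the
    resampling differentiable."""
    T = len(ts)
    if T == 1:
        return np.ones((n_grid, 1))
    tau = (ts - ts[0]) / (ts[-1] - ts[0])
    grid = np.linspace(0.0, 1.0, n_grid)
    M = np.zeros((n_grid, T))
    idx = np.clip(np.searchsorted(tau, grid, side="right") - 1, 0, T - 2)
    w = (grid - tau[idx]) / (tau[idx + 1] - tau[idx])
    for g in range(n_grid):
        M[g, idx[g]] = 1.0 - w[g]
        M[g, idx[g] + 1] = w[g]
    return M


def _nearest_state_index(ts: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(ts - t)))


def named_tensors(model: Model) -> dict[str, Tensor]:
    """Stable name -> tensor map over every learnable leaf of the model."""
    out: dict[str, Tensor] = {}

    def put(name, t):
        if isinstance(t, Tensor):
            out[name] = t

    for i, (W, b) in enumerate(model.enc.phi_x):
        put(f"enc.phi_x.{i}.W", W); put(f"enc.phi_x.{i}.b", b)
    for i, (W, b) in enumerate(model.enc.phi_e):
        put(f"enc.phi_e.{i}.W", W); put(f"enc.phi_e.{i}.b", b)
    for i, (W, b) in enumerate(model.enc.phi_a):
        put(f"enc.phi_a.{i}.W", W); put(f"enc.phi_a.{i}.b", b)
    for i, W in enumerate(model.enc.W_layers):
        put(f"enc.W_layers.{i}", W)
    for name in ("psi_attn", "w_g", "b_g", "W_s", "b_s", "eta", "lambda_sim"):
        put(f"enc.{name}", getattr(model.enc, name))
    for name in ("q", "W_q", "W_f", "b_f", "obs_scale"):
        put(f"fus.{name}", getattr(model.fus, name))
    for pfx, gru in (("fus.gru_fwd", model.fus.gru_fwd), ("fus.gru_bwd", model.fus.gru_bwd)):
        for k, t in sorted(gru.items()):
            put(f"{pfx}.{k}", t)
    put("head.W", model.head.W); put("head.b", model.head.b)
    put("proj.W", model.proj.W); put("proj.b", model.proj.b)
    for lab, c in sorted(model.anchors.centers.items()):
        put(f"anchors.{lab}", c)
    return out


def save_checkpoint(model: Model, config: RunConfig, path: str) -> None:
    blob = {
        "format_version": 1,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "event_labels": sorted(model.anchors.centers),
        "action_labels": model.registry.names(),
        "tensors": {k: t.data.tolist() for k, t in named_tensors(model).items()},
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_checkpoint(path: str) -> tuple[Model, RunConfig]:
    with open(path) as fh:
        blob = json.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError(f"unrecognized checkpoint format: {blob.get('format_version')}")
    cfg_dict = blob["config"]
    cfg_dict["strides"] = tuple(cfg_dict["strides"])
    cfg_dict["curriculum"] = [(e, o) for e, o in cfg_dict["curriculum"]]
    config = RunConfig(**cfg_dict)
    model = init_model(config, blob["event_labels"], blob["action_labels"])
    names = named_tensors(model)
    for k, v in blob["tensors"].items():
        names[k].data = np.asarray(v, dtype=np.float64).reshape(names[k].data.shape)
    return model, config


def _forward_cohort(model: Model, cohort, graphs, config: RunConfig):
    """Encode every patient and run batched fusion; returns per-patient
    dicts with fused (h_tilde), final states s, and the encoder state."""
    enc_states = [enc_mod.encode(g, traj, model.enc)
                  for g, traj in zip(graphs, cohort)]
    results = [None] * len(cohort)
    by_len: dict[int, list[int]] = {}
    for i, st in enumerate(enc_states):
        by_len.setdefault(st.fused.data.shape[0], []).append(i)
    for T, idxs in sorted(by_len.items()):
        H3 = ad.stack([enc_states[i].fused for i in idxs], axis=0)
        r3, b3 = fus_mod.bidirectional_context_batch(H3, model.fus)
        B = len(idxs)
        cat = ad.concat([r3, b3], axis=2)
        c3 = ad.reshape(
            ad.matmul(ad.reshape(cat, (B * T, 2 * config.D)),
                      ad.transpose(model.fus.W_f)) + model.fus.b_f,
            (B, T, config.D))
        s3 = H3 + c3
        for j, i in enumerate(idxs):
            results[i] = {"enc": enc_states[i], "h_tilde": H3[j], "s": s3[j]}
    return results


def _prediction_loss(results, cohort, model: Model, config: RunConfig):
    h = config.horizon
    terms, count = [], 0
    for res, traj in zip(results, cohort):
        T = traj.n_steps
        if T <= h:
            continue
        s_head = res["s"][:T - h]
        pred = ad.matmul(s_head, ad.transpose(model.head.W)) + model.head.b
        if config.forecast_mode == "residual":
            pred = pred + traj.states[:T - h]
        resid = pred - traj.states[h:]
        err = resid ** 2 if config.loss_type == "mse" else ad.absolute(resid)
        if config.risk_center is not None:
            w_t = np.exp(-((traj.timestamps[h:] - config.risk_center) ** 2)
                         / (2 * config.risk_sigma ** 2))
            err = err * w_t.reshape(-1, 1)
        terms.append(ad.tsum(err))
        count += (T - h) * traj.d
    if not terms:
        raise ValueError("no trajectory is longer than the forecast horizon")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / count)


def _structural_losses(results, cohort, graphs, model: Model, config: RunConfig,
                       priors: dict[str, np.ndarray] | None,
                       condition: dict[str, str], rng: np.random.Generator):
    n = len(cohort)
    comp: dict[str, Tensor] = {}

    def mean_terms(terms):
        if not terms:
            return Tensor(0.0)
        acc = terms[0]
        for t in terms[1:]:
            acc = acc + t
        return acc * (1.0 / len(terms))

    arc_terms, geom_terms, stage_terms, lap_terms, prior_terms = [], [], [], [], []
    for res, traj, graph in zip(results, cohort, graphs):
        s = res["s"]
        ts = traj.timestamps
        # multi-resolution: full sequence plus strided subsequences; every
        # term is averaged over its constraint set so weights are scale-free
        for stride in config.strides:
            n_sub = len(ts[::stride])
            if n_sub >= 2:
                arc_terms.append(obj.arc_length_loss(s[::stride], ts[::stride])
                                 * (1.0 / (n_sub - 1)))
                pairs = fus_mod.consistency_pairs(ts[::stride],
                                                  config.n_geom_random_pairs, rng)
                geom_terms.append(fus_mod.geometry_penalty(s, traj, model.fus, pairs)
                                  * (1.0 / len(pairs)))
        if traj.n_steps >= config.K:
            seg = obj.stage_statistics(s, config.K)
            stage_terms.append(obj.stage_separation_loss(seg)
                               * (2.0 / (config.K * (config.K - 1))
                                  if config.K > 1 else 1.0))
        lap_terms.append(obj.laplacian_smoothness(res["enc"].aggregated, graph)
                         * (1.0 / max(len(graph.edges), 1)))
        p_t = priors.get(traj.patient_id) if priors else traj.states
        prior_terms.append(obj.prior_loss(s, model.proj, p_t) * (1.0 / traj.n_steps))

    comp["arc"] = mean_terms(arc_terms)
    comp["geometry"] = mean_terms(geom_terms)
    comp["stage_sep"] = mean_terms(stage_terms)
    comp["laplacian"] = mean_terms(lap_terms)
    comp["prior"] = mean_terms(prior_terms)

    # cross-patient alignment among patients sharing a condition label
    groups: dict[str, list[int]] = {}
    for i, traj in enumerate(cohort):
        groups.setdefault(condition.get(traj.patient_id, "cohort"), []).append(i)
    align_terms, soft_terms = [], []
    eligible = [g for g in groups.values() if len(g) >= 2]
    for _ in range(config.n_align_pairs if eligible else 0):
        g = eligible[int(rng.integers(len(eligible)))]
        i, j = rng.choice(len(g), size=2, replace=False)
        p, q = g[int(i)], g[int(j)]
        Mp = _interp_matrix(cohort[p].timestamps, config.n_grid)
        Mq = _interp_matrix(cohort[q].timestamps, config.n_grid)
        sp = ad.matmul(Tensor(Mp), results[p]["s"])
        sq = ad.matmul(Tensor(Mq), results[q]["s"])
        align_terms.append(obj.alignment_loss(sp, sq) * (1.0 / config.n_grid))
        pi = obj.nearest_index_alignment(cohort[p].timestamps, cohort[q].timestamps)
        soft_terms.append(obj.soft_alignment_loss(results[p]["s"], results[q]["s"], pi)
                          * (1.0 / cohort[p].n_steps))
    comp["align"] = mean_terms(align_terms)
    comp["soft_align"] = mean_terms(soft_terms)

    # event anchors
    anchor_terms = []
    for res, traj in zip(results, cohort):
        for ev in traj.events:
            k = _nearest_state_index(traj.timestamps, ev.time)
            anchor_terms.append(
                obj.event_anchor_loss(res["s"][k], model.anchors, ev.label))
    comp["event_anchor"] = mean_terms(anchor_terms)
    n_lab = len(model.anchors.centers)
    n_anchor_pairs = max(n_lab * (n_lab - 1) // 2, 1)
    comp["anchor_sep"] = ad.as_tensor(obj.anchor_separation_loss(model.anchors)) \
        * (1.0 / n_anchor_pairs)

    # counterfactual intervention orientation on a seeded subsample; the
    # modified sequences are re-fused as one GRU batch per sequence length
    cand = [(i, a) for i, traj in enumerate(cohort) for a in traj.actions
            if _nearest_state_index(traj.timestamps, a.time) + 1 < traj.n_steps]
    interv_terms = []
    if cand:
        take = min(config.interventions_per_batch, len(cand))
        chosen = sorted(int(c) for c in rng.choice(len(cand), size=take, replace=False))
        groups: dict[int, list] = {}
        for ci in chosen:
            i, action = cand[ci]
            traj = cohort[i]
            t_idx = _nearest_state_index(traj.timestamps, action.time)
            tp_idx = t_idx + 1
            dt = float(traj.timestamps[tp_idx] - action.time)
            H = results[i]["h_tilde"]
            h_hat = enc_mod.simulate_intervention(H[t_idx], action.features, dt,
                                                  model.enc)
            parts = [p for p in (H[:tp_idx], ad.reshape(h_hat, (1, config.D)),
                                 H[tp_idx + 1:]) if p.data.shape[0] > 0]
            H_mod = ad.concat(parts, axis=0)
            groups.setdefault(traj.n_steps, []).append((i, action, tp_idx, dt, H_mod))
        for T, items in sorted(groups.items()):
            H3 = ad.stack([it[4] for it in items], axis=0)
            r3, b3 = fus_mod.bidirectional_context_batch(H3, model.fus)
            cat = ad.concat([r3, b3], axis=2)
            B = len(items)
            c3 = ad.reshape(
                ad.matmul(ad.reshape(cat, (B * T, 2 * config.D)),
                          ad.transpose(model.fus.W_f)) + model.fus.b_f,
                (B, T, config.D))
            s3 = H3 + c3
            for j, (i, action, tp_idx, dt, _) in enumerate(items):
                delta = obj.intervention_effect(s3[j, tp_idx],
                                                results[i]["s"][tp_idx])
                interv_terms.append(obj.intervention_orientation_loss(
                    delta, action.features, dt, model.registry,
                    action.label or "action"))
    comp["interv_orient"] = mean_terms(interv_terms)
    return comp


def train(cohort: list[PatientTrajectory], config: RunConfig,
          ground_truth: CohortGroundTruth | None = None,
          priors_table: CausalPriorTable | None = None,
          prior_targets: dict[str, np.ndarray] | None = None,
          ) -> tuple[Model, list[obj.LossBundle]]:
    """Train the full model on a cohort; returns (model, per-epoch history).

    ``ground_truth`` (when available, e.g. from the synthetic generator)
    supplies condition labels for alignment pairing and noiseless states as
    clinical-prior targets; without it all patients form one pairing group
    and the observed states serve as prior targets.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    d = cohort[0].d
    if d != config.d:
        raise ValueError(f"cohort state dimension {d} != config.d={config.d}")
    event_labels = sorted({e.label for traj in cohort for e in traj.events})
    action_labels = sorted({a.label or "action" for traj in cohort for a in traj.actions})
    model = init_model(config, event_labels, action_labels)
    graphs = [build_graph(traj, priors_table, window=config.graph_window)
              for traj in cohort]
    condition = ground_truth.condition if ground_truth else {}
    if prior_targets is None and ground_truth is not None:
        prior_targets = {pid: c for pid, c in ground_truth.clean_states.items()}

    params = list(named_tensors(model).values())
    params = [p for p in params if p.requires_grad]
    opt = ad.Adam(params, lr=config.lr)
    history: list[obj.LossBundle] = []

    order = list(range(len(cohort)))
    batch = config.batch_size if config.batch_size > 0 else len(cohort)

    for epoch in range(config.epochs):
        weights = curriculum_weights(epoch, config)
        epoch_vals: dict[str, list[float]] = {}
        epoch_total = 0.0
        n_batches = 0
        for lo in range(0, len(order), batch):
            # structural subsample is a function of (seed, batch) only, so the
            # optimized objective is the same deterministic function each epoch
            rng = np.random.default_rng((config.seed * 100003 + lo) % (2 ** 31))
            idxs = order[lo:lo + batch]
            sub = [cohort[i] for i in idxs]
            sub_graphs = [graphs[i] for i in idxs]
            results = _forward_cohort(model, sub, sub_graphs, config)
            comp = {"prediction": _prediction_loss(results, sub, model, config)}
            comp.update(_structural_losses(results, sub, sub_graphs, model, config,
                                           prior_targets, condition, rng))
            bundle = obj.total_objective(comp, weights)
            for name, v in bundle.values.items():
                if not np.isfinite(v):
                    raise RuntimeError(
                        f"non-finite loss component {name!r} at epoch {epoch}")
            if bundle.total_tensor is not None:
                opt.zero_grad()
                ad.backward(bundle.total_tensor)
                opt.step()
            for k, v in bundle.values.items():
                epoch_vals.setdefault(k, []).append(v)
            epoch_total += bundle.total
            n_batches += 1
        mean_vals = {k: float(np.mean(v)) for k, v in epoch_vals.items()}
        history.append(obj.LossBundle(values=mean_vals, weights=dict(weights),
                                      total=epoch_total / n_batches))
    return model, history


def fit_simulation_operator(h: np.ndarray, u: np.ndarray, dt: np.ndarray,
                            y: np.ndarray, seed: int, steps: int = 3000,
                            lr: float = 0.02) -> dict[str, float]:
    """Fit the counterfactual simulation operator to observed responses.

    Minimizes the MSE between S(h, u, dt) and y over (eta, lambda_sim,
    W_s, b_s) with Adam.  The raw amplitude eta and the saturation level of
    the tanh term are only jointly identified (they enter as a product), so
    the returned ``eta_eff`` is the identifiable effective amplitude
    eta * mean ||tanh(W_s [h||u] + b_s)||_2 — directly comparable to the
    amplitude of a unit-direction generative kernel — alongside the decay
    ``lambda_sim``.
    """
    n, D = h.shape
    d_a = u.shape[1]
    params = enc_mod.EncoderParams.create(d=D, d_e=1, d_a=d_a, D=D, L=1,
                                          seed=seed, eta=0.3, lambda_sim=0.2)
    fit = [params.eta, params.lambda_sim, params.W_s, params.b_s]
    opt = ad.Adam(fit, lr=lr)
    hT, uT = Tensor(h), Tensor(u)
    for _ in range(steps):
        pred = enc_mod.simulate_intervention(hT, uT, dt, params)
        loss = ad.tmean((pred - y) ** 2)
        opt.zero_grad()
        ad.backward(loss)
        opt.step()
        # decay and amplitude are nonnegative by definition
        params.eta.data = np.maximum(params.eta.data, 0.0)
        params.lambda_sim.data = np.maximum(params.lambda_sim.data, 0.0)
    pre = np.concatenate([h, u], axis=1) @ params.W_s.data.T + params.b_s.data
    sat = float(np.mean(np.linalg.norm(np.tanh(pre), axis=1)))
    return {
        "eta_eff": float(params.eta.data) * sat,
        "lambda_sim": float(params.lambda_sim.data),
        "eta_raw": float(params.eta.data),
        "mse": float(np.mean((enc_mod.simulate_intervention(
            hT, uT, dt, params).data - y) ** 2)),
    }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    rmse: float) -> dict[str, float]:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "rmse": float(rmse),
    }


def evaluate(model: Model, cohort: list[PatientTrajectory], config: RunConfig,
             ground_truth: CohortGroundTruth | None = None,
             priors_table: CausalPriorTable | None = None) -> dict[str, float]:
    """Forecast every trajectory and score anomaly detection + RMSE.

    A step is classified anomalous when the forecast-residual norm exceeds
    ``config.anomaly_threshold``; reference labels come from the cohort's
    ground-truth annotations (rule on the designated channel).
    """
    graphs = [build_graph(traj, priors_table, window=config.graph_window)
              for traj in cohort]
    results = _forward_cohort(model, cohort, graphs, config)
    h = config.horizon
    y_true, y_pred, sq_errs = [], [], []
    for res, traj in zip(results, cohort):
        if traj.n_steps <= h:
            continue
        pred = (res["s"][:traj.n_steps - h].data @ model.head.W.data.T
                + model.head.b.data)
        if config.forecast_mode == "residual":
            pred = pred + traj.states[:traj.n_steps - h]
        actual = traj.states[h:]
        resid = np.linalg.norm(pred - actual, axis=1)
        sq_errs.append(((pred - actual) ** 2).ravel())
        y_pred.append(resid > config.anomaly_threshold)
        if ground_truth is not None:
            y_true.append(ground_truth.anomaly_labels[traj.patient_id][h:])
        else:
            y_true.append(np.zeros(traj.n_steps - h, dtype=bool))
    rmse = float(np.sqrt(np.mean(np.concatenate(sq_errs))))
    return compute_metrics(np.concatenate(y_true), np.concatenate(y_pred), rmse)
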