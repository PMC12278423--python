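"""Seeded synthetic cardiovascular cohorts with known ground truth.

Each patient follows stable linear latent dynamics

    x_{t+1} = A x_t + drift + eps_t,        spectral_radius(A) < 1,

sampled at a fixed interval, with i.i.d. Gaussian per-step variability
eps_t of standard deviation ``noise_sd`` (heart-rate/HRV channels are
intrinsically stochastic, so the noise lives in the transition; the
noise-free skeleton of the same recursion is kept as ground truth and
serves as the clinical-prior target).  Discrete
clinical events fire per-step with label-specific rates; intervention
actions inject an additive response

    eta* . exp(-lambda* . (t - rho_j)) . direction      (t > rho_j)

into all subsequent states — the same amplitude-decay form as the
encoder's simulation operator, which makes recovery of (eta*, lambda*)
from generated responses well-posed.  Anomaly labels are a fixed threshold
rule on a designated channel, so they can be re-derived from the emitted
states.  Channel conventions (by index): 0 heart rate proxy, 1 HRV proxy,
2 systolic BP proxy, 3 sympathetic-tone proxy, remaining channels generic.

The generator is the study-condition oracle for the whole test suite: it
emulates the *structure* of multimodal cardiovascular records (irregular
discrete events, delayed pharmacodynamic responses, noisy observations),
not the morphology of real ECG/PPG signals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .domain import (ActionRecord, CausalPriorRule, CausalPriorTable,
                     EventRecord, PatientTrajectory)

__all__ = [
    "InterventionKernel", "SyntheticCohortSpec", "CohortGroundTruth",
    "generate_cohort", "make_prior_table", "make_priors_for_prior_loss",
    "stable_linear_map",
]


@dataclass(frozen=True)
class InterventionKernel:
    """Additive response kernel of one intervention label."""

    eta: float
    lam: float
    direction: np.ndarray      # unit-norm direction in state space

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("kernel direction must be nonzero")
        object.__setattr__(self, "direction", d / norm)
        if self.eta < 0 or self.lam < 0:
            raise ValueError("kernel eta and lam must be >= 0")

    def response(self, dt) -> np.ndarray:
        dt = np.asarray(dt, dtype=np.float64)
        return self.eta * np.exp(-self.lam * dt)[..., None] * self.direction


def stable_linear_map(d: int, seed: int, radius: float = 0.9,
                      angle: float = 0.35) -> np.ndarray:
    """Stable coupling matrix with damped-oscillatory structure.

    Channel pairs (0,2) and (1,3) form 2x2 damped rotation blocks (a
    baroreflex-like heart-rate/blood-pressure interplay with a period of
    ~2*pi/angle steps); remaining channels decay geometrically.  A small
    random coupling is added and the matrix is rescaled to the requested
    spectral radius, so trajectories are smooth but not persistence-trivial.
    """
    rng = np.random.default_rng(seed)
    A = 0.8 * np.eye(d)
    rot = radius * np.array([[np.cos(angle), -np.sin(angle)],
                             [np.sin(angle), np.cos(angle)]])
    for (i, j) in ((0, 2), (1, 3)):
        if j < d:
            A[np.ix_([i, j], [i, j])] = rot
    A += rng.normal(0, 0.02, size=(d, d))
    rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    return A * (radius / rho)


@dataclass
class SyntheticCohortSpec:
    """Generator parameters; defaults define the package's study conditions."""

    n_patients: int = 50
    steps: int = 100
    dt: float = 5.0                   # sampling interval, seconds
    d: int = 6
    d_e: int = 3
    d_a: int = 3
    A: np.ndarray | None = None       # stable linear map; built from seed if None
    drift: np.ndarray | None = None
    noise_sd: float = 0.05
    event_rate: dict[str, float] = field(default_factory=lambda: {
        "tachycardia_alert": 0.02, "hypotension_alert": 0.02})
    intervention_rate: dict[str, float] = field(default_factory=lambda: {
        "beta_blocker": 0.015})
    kernels: dict[str, InterventionKernel] | None = None
    anomaly_channel: int = 0
    anomaly_threshold: float = 0.25   # ~2 stationary sd of the channel
    condition_labels: tuple[str, ...] = ("typical", "asd_like")
    asd_hrv_shrink: float = 0.4       # variance shrink factor on the HRV channel
    asd_sympathetic_shift: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.steps < 1 or self.d < 1:
            raise ValueError("n_patients, steps and d must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, r in {**self.event_rate, **self.intervention_rate}.items():
            if not 0 <= r <= 1:
                raise ValueError(f"rate for {name!r} must be in [0, 1]")
        if self.A is None:
            self.A = stable_linear_map(self.d, self.seed + 101)
        else:
            self.A = np.asarray(self.A, dtype=np.float64)
        rho = float(np.max(np.abs(np.linalg.eigvals(self.A))))
        if rho >= 1:
            raise ValueError(f"A must be stable; spectral radius {rho:.3f} >= 1")
        if self.drift is None:
            self.drift = np.zeros(self.d)
        else:
            self.drift = np.asarray(self.drift, dtype=np.float64)
        if self.kernels is None:
            rng = np.random.default_rng(self.seed + 202)
            self.kernels = {}
            for label in self.intervention_rate:
                direction = rng.normal(size=self.d)
                self.kernels[label] = InterventionKernel(
                    eta=0.8, lam=0.5, direction=direction)
        if not 0 <= self.anomaly_channel < self.d:
            raise ValueError("anomaly_channel outside state dimensions")


@dataclass
class CohortGroundTruth:
    """Everything the generator knows that an analyst normally would not."""

    clean_states: dict[str, np.ndarray]      # noise-free skeleton + responses
    anomaly_labels: dict[str, np.ndarray]    # bool per time step per patient
    condition: dict[str, str]                # condition label per patient
    kernels: dict[str, InterventionKernel]


def _label_embedding(label: str, dim: int) -> np.ndarray:
    """Deterministic feature prototype for a categorical label."""
    digest = zlib.crc32(label.encode("utf-8"))
    rng = np.random.default_rng(digest % (2 ** 31))
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[list[PatientTrajectory], CohortGroundTruth]:
    """Generate a seeded cohort plus its ground-truth annotations."""
    rng = np.random.default_rng(spec.seed)
    ev_protos = {lab: _label_embedding("event:" + lab, spec.d_e)
                 for lab in spec.event_rate}
    ac_protos = {lab: _label_embedding("action:" + lab, spec.d_a)
                 for lab in spec.intervention_rate}

    cohort: list[PatientTrajectory] = []
    clean_states: dict[str, np.ndarray] = {}
    anomaly: dict[str, np.ndarray] = {}
    condition: dict[str, str] = {}

    for i in range(spec.n_patients):
        pid = f"p{i:04d}"
        cond = spec.condition_labels[i % len(spec.condition_labels)]
        ts = np.arange(spec.steps, dtype=np.float64) * spec.dt

        x = rng.normal(0, 0.3, size=spec.d)
        drift = spec.drift.copy()
        noise_scale = np.ones(spec.d)
        if cond == "asd_like" and spec.d > 3:
            # structural emulation of reduced HRV + sympathetic dominance:
            # shrink HRV-channel variability, shift sympathetic-proxy baseline
            x[1] *= spec.asd_hrv_shrink
            noise_scale[1] = spec.asd_hrv_shrink
            drift[3] += spec.asd_sympathetic_shift * 0.1
        # noisy recursion (per-step physiological variability) alongside the
        # deterministic skeleton used as the clinical-prior target
        skel = x.copy()
        base = np.empty((spec.steps, spec.d))
        base_skel = np.empty((spec.steps, spec.d))
        for t in range(spec.steps):
            base[t] = x
            base_skel[t] = skel
            eps = rng.normal(0, spec.noise_sd, size=spec.d) * noise_scale
            x = spec.A @ x + drift + eps
            skel = spec.A @ skel + drift

        events: list[EventRecord] = []
        for t_idx in range(spec.steps):
            for lab, rate in spec.event_rate.items():
                if rng.random() < rate:
                    z = ev_protos[lab] + rng.normal(0, 0.1, size=spec.d_e)
                    events.append(EventRecord(time=float(ts[t_idx]), features=z,
                                              label=lab))
        actions: list[ActionRecord] = []
        for t_idx in range(spec.steps):
            for lab, rate in spec.intervention_rate.items():
                if rng.random() < rate:
                    u = ac_protos[lab] + rng.normal(0, 0.1, size=spec.d_a)
                    actions.append(ActionRecord(time=float(ts[t_idx]), features=u,
                                                label=lab))

        obs = base.copy()
        clean = base_skel.copy()
        for a in actions:
            k = spec.kernels[a.label]
            after = ts > a.time
            resp = k.response(ts[after] - a.time)
            obs[after] += resp
            clean[after] += resp
        if not np.all(np.isfinite(obs)):
            raise FloatingPointError(f"patient {pid}: non-finite states generated")

        cohort.append(PatientTrajectory(
            patient_id=pid, timestamps=ts, states=obs, events=events,
            actions=actions, episode_duration=float(ts[-1])))
        clean_states[pid] = clean
        anomaly[pid] = obs[:, spec.anomaly_channel] > spec.anomaly_threshold
        condition[pid] = cond

    gt = CohortGroundTruth(clean_states=clean_states, anomaly_labels=anomaly,
                           condition=condition, kernels=dict(spec.kernels))
    return cohort, gt


def generate_intervention_responses(kernel: InterventionKernel, n: int, D: int,
                                    d_a: int, seed: int, noise_sd: float = 0.0,
                                    dt_max: float = 10.0):
    """Sample n (h, u, dt, y) tuples with y = h + kernel response at dt.

    The pre-intervention latent states h and action features u are random;
    dt is uniform on [0, dt_max].  This is the identifiable fitting problem
    for the simulation operator's amplitude and decay.
    """
    if kernel.direction.shape[0] != D:
        raise ValueError("kernel direction dimension must equal D")
    rng = np.random.default_rng(seed)
    h = rng.normal(0, 1.0, size=(n, D))
    u = rng.normal(0, 1.0, size=(n, d_a))
    dt = rng.uniform(0, dt_max, size=n)
    y = h + kernel.response(dt) + rng.normal(0, noise_sd, size=(n, D))
    return h, u, dt, y


def make_prior_table(spec: SyntheticCohortSpec) -> CausalPriorTable:
    """Causal-prior rules linking each intervention label to state nodes
    within 3 / lambda* seconds (three decay time constants)."""
    rules = [
        CausalPriorRule(src_kind="action", src_label=lab, dst_kind="state",
                        dst_label="*", max_lag=3.0 / k.lam, weight=1.0)
        for lab, k in sorted(spec.kernels.items()) if k.lam > 0
    ] if spec.intervention_rate else []
    return CausalPriorTable(rules=rules)


def make_priors_for_prior_loss(gt: CohortGroundTruth) -> dict[str, np.ndarray]:
    """Clinical-prior targets p_t for the pathway-constraint loss: the
    noiseless generative states."""
    return {pid: clean.copy() for pid, clean in gt.clean_states.items()}
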