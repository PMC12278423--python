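import numpy as np
import pytest

from cardiograph import autodiff as ad
from cardiograph.domain import (ActionRecord, CausalPriorRule, CausalPriorTable,
                                EventRecord, PatientTrajectory, build_graph)
from cardiograph.encoder import EncoderParams
from cardiograph.fusion import FusionParams


@pytest.fixture
def tiny_traj() -> PatientTrajectory:
    """3 states, 1 event, 1 action on a 20 s episode."""
    return PatientTrajectory(
        patient_id="tiny",
        timestamps=np.array([0.0, 5.0, 10.0]),
        states=np.array([[0.1, 0.2], [0.3, 0.1], [0.2, 0.4]]),
        events=[EventRecord(time=4.0, features=np.array([1.0, 0.0]), label="alert")],
        actions=[ActionRecord(time=6.0, features=np.array([0.5]), label="dose")],
        episode_duration=20.0,
    )


@pytest.fixture
def tiny_graph(tiny_traj):
    return build_graph(tiny_traj, CausalPriorTable(), window=6.0)


@pytest.fixture
def enc_params() -> EncoderParams:
    return EncoderParams.create(d=2, d_e=2, d_a=1, D=4, L=2, seed=42)


@pytest.fixture
def fus_params() -> FusionParams:
    return FusionParams.create(D=4, seed=43)


def random_trajectory(rng: np.random.Generator, n_states: int = 5, d: int = 2,
                      n_events: int = 1, n_actions: int = 1,
                      d_e: int = 2, d_a: int = 1) -> PatientTrajectory:
    """Random well-formed trajectory for property tests."""
    ts = np.sort(rng.uniform(0, 30, size=n_states))
    ts += np.arange(n_states) * 1e-3  # enforce strict increase
    T = float(ts[-1] + 5)
    events = [EventRecord(time=float(rng.uniform(0, T)),
                          features=rng.normal(size=d_e), label="e")
              for _ in range(n_events)]
    actions = [ActionRecord(time=float(rng.uniform(0, T)),
                            features=rng.normal(size=d_a), label="a")
               for _ in range(n_actions)]
    return PatientTrajectory(patient_id=f"r{rng.integers(1 << 30)}",
                             timestamps=ts, states=rng.normal(size=(n_states, d)),
                             events=events, actions=actions, episode_duration=T)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def assert_grads_match(loss_fn, tensors: dict[str, ad.Tensor],
                       tol: float = 1e-3) -> None:
    """loss_fn() -> Tensor scalar; checks backward grads of each named tensor
    against central differences."""
    out = loss_fn()
    for t in tensors.values():
        t.grad = None
    ad.backward(out)
    for name, t in tensors.items():
        num = numeric_gradient(lambda: float(loss_fn().data), t.data)
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        scale = max(np.abs(num).max(), np.abs(ana).max(), 1e-8)
        err = np.abs(ana - num).max() / scale
        assert err < tol, f"gradient mismatch for {name}: rel err {err:.2e}"
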