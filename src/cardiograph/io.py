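"""Readers/writers for cohort and prior-table files, config parsing, run logs.

Cohort records travel as JSONL (one patient per line, canonical key order,
shortest-round-trip float formatting, so write -> read -> write is stable
byte-for-byte) or as a trio of CSV files keyed by patient_id.  Config files
are YAML mirroring RunConfig; unknown keys are rejected rather than
silently ignored.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .domain import (ActionRecord, CausalPriorRule, CausalPriorTable,
                     EventRecord, PatientTrajectory)
from .synthetic import CohortGroundTruth, InterventionKernel
from .training import RunConfig

__all__ = [
    "CohortFile", "read_cohort", "write_cohort", "read_prior_table",
    "write_prior_table", "validate_config", "log_run",
    "write_ground_truth", "read_ground_truth",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CohortFile:
    path: str
    format: str = "jsonl"      # "jsonl" | "csv-trio" (path is the directory)

    def __post_init__(self):
        if self.format not in ("jsonl", "csv-trio"):
            raise ValueError(f"unknown cohort format {self.format!r}")


def _record(traj: PatientTrajectory) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_id": traj.patient_id,
        "T": float(traj.episode_duration),
        "states": [{"t": float(t), "x": [float(v) for v in x]}
                   for t, x in zip(traj.timestamps, traj.states)],
        "events": [{"t": float(e.time), "z": [float(v) for v in e.features],
                    "label": e.label} for e in traj.events],
        "actions": [{"t": float(a.time), "u": [float(v) for v in a.features],
                     "label": a.label} for a in traj.actions],
    }


def _parse_record(rec: dict, lineno: int) -> PatientTrajectory:
    pid = rec.get("patient_id", f"<line {lineno}>")
    version = rec.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"record {pid!r} (line {lineno}): unknown schema "
                         f"version {version!r}")
    try:
        return PatientTrajectory(
            patient_id=rec["patient_id"],
            timestamps=np.array([s["t"] for s in rec["states"]]),
            states=np.array([s["x"] for s in rec["states"]], dtype=np.float64),
            events=[EventRecord(time=e["t"], features=np.array(e["z"]),
                                label=e["label"]) for e in rec["events"]],
            actions=[ActionRecord(time=a["t"], features=np.array(a["u"]),
                                  label=a.get("label", "")) for a in rec["actions"]],
            episode_duration=rec.get("T"),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"record {pid!r} (line {lineno}): {exc}") from exc


def write_cohort(cohort: list[PatientTrajectory], file: CohortFile | str) -> None:
    file = CohortFile(file) if isinstance(file, str) else file
    if file.format == "jsonl":
        with open(file.path, "w") as fh:
            for traj in cohort:
                fh.write(json.dumps(_record(traj), sort_keys=True) + "\n")
        return
    root = Path(file.path)
    root.mkdir(parents=True, exist_ok=True)
    srows, erows, arows = [], [], []
    for traj in cohort:
        for t, x in zip(traj.timestamps, traj.states):
            srows.append({"patient_id": traj.patient_id, "t": float(t),
                          **{f"x{i}": float(v) for i, v in enumerate(x)}})
        for e in traj.events:
            erows.append({"patient_id": traj.patient_id, "t": float(e.time),
                          "label": e.label,
                          **{f"z{i}": float(v) for i, v in enumerate(e.features)}})
        for a in traj.actions:
            arows.append({"patient_id": traj.patient_id, "t": float(a.time),
                          "label": a.label,
                          **{f"u{i}": float(v) for i, v in enumerate(a.features)}})
    pd.DataFrame(srows).to_csv(root / "states.csv", index=False)
    pd.DataFrame(erows).to_csv(root / "events.csv", index=False)
    pd.DataFrame(arows).to_csv(root / "actions.csv", index=False)


def read_cohort(file: CohortFile | str) -> list[PatientTrajectory]:
    file = CohortFile(file) if isinstance(file, str) else file
    if file.format == "jsonl":
        cohort = []
        with open(file.path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: invalid JSON: {exc}") from exc
                cohort.append(_parse_record(rec, lineno))
        return cohort
    root = Path(file.path)
    states = pd.read_csv(root / "states.csv")
    events = pd.read_csv(root / "events.csv") if (root / "events.csv").exists() \
        else pd.DataFrame(columns=["patient_id", "t", "label"])
    actions = pd.read_csv(root / "actions.csv") if (root / "actions.csv").exists() \
        else pd.DataFrame(columns=["patient_id", "t", "label"])
    xcols = sorted([c for c in states.columns if c.startswith("x")],
                   key=lambda c: int(c[1:]))
    zcols = sorted([c for c in events.columns if c.startswith("z")],
                   key=lambda c: int(c[1:]))
    ucols = sorted([c for c in actions.columns if c.startswith("u")],
                   key=lambda c: int(c[1:]))
    cohort = []
    for pid, grp in states.groupby("patient_id", sort=True):
        grp = grp.sort_values("t")
        ev = events[events.patient_id == pid].sort_values("t") if len(events) else events
        ac = actions[actions.patient_id == pid].sort_values("t") if len(actions) else actions
        try:
            cohort.append(PatientTrajectory(
                patient_id=str(pid),
                timestamps=grp["t"].to_numpy(),
                states=grp[xcols].to_numpy(dtype=np.float64),
                events=[EventRecord(time=float(r.t), label=str(r.label),
                                    features=np.array([getattr(r, c) for c in zcols]))
                        for r in ev.itertuples()],
                actions=[ActionRecord(time=float(r.t), label=str(r.label),
                                      features=np.array([getattr(r, c) for c in ucols]))
                         for r in ac.itertuples()],
            ))
        except ValueError as exc:
            raise ValueError(f"patient {pid!r}: {exc}") from exc
    return cohort


def write_prior_table(table: CausalPriorTable, path: str) -> None:
    rows = [{"src_kind": r.src_kind, "src_label": r.src_label,
             "dst_kind": r.dst_kind, "dst_label": r.dst_label,
             "max_lag_s": r.max_lag, "weight": r.weight}
            for r in table.rules]
    pd.DataFrame(rows, columns=["src_kind", "src_label", "dst_kind", "dst_label",
                                "max_lag_s", "weight"]).to_csv(path, index=False)


def read_prior_table(path: str) -> CausalPriorTable:
    df = pd.read_csv(path)
    required = {"src_kind", "src_label", "dst_kind", "dst_label", "max_lag_s", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prior table {path}: missing columns {sorted(missing)}")
    rules = [CausalPriorRule(src_kind=r.src_kind, src_label=r.src_label,
                             dst_kind=r.dst_kind, dst_label=r.dst_label,
                             max_lag=float(r.max_lag_s), weight=float(r.weight))
             for r in df.itertuples()]
    return CausalPriorTable(rules=rules)


def validate_config(text: str) -> RunConfig:
    """Parse a YAML run config; apply defaults; reject unknown keys."""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config key 'seed' is required")
    if "loss_weights" in raw:
        base = RunConfig(seed=0).loss_weights
        base.update(raw["loss_weights"])
        raw["loss_weights"] = base
    if "curriculum" in raw:
        raw["curriculum"] = [(int(e), dict(o)) for e, o in raw["curriculum"]]
    if "strides" in raw:
        raw["strides"] = tuple(raw["strides"])
    return RunConfig(**raw)


def write_ground_truth(gt: CohortGroundTruth, path: str) -> None:
    blob = {
        "patients": {pid: {"clean": gt.clean_states[pid].tolist(),
                           "anomaly": gt.anomaly_labels[pid].astype(int).tolist(),
                           "condition": gt.condition[pid]}
                     for pid in sorted(gt.clean_states)},
        "kernels": {lab: {"eta": k.eta, "lam": k.lam,
                          "direction": k.direction.tolist()}
                    for lab, k in sorted(gt.kernels.items())},
    }
    with open(path, "w") as fh:
        json.dump(blob, fh, sort_keys=True)


def read_ground_truth(path: str) -> CohortGroundTruth:
    with open(path) as fh:
        blob = json.load(fh)
    return CohortGroundTruth(
        clean_states={pid: np.asarray(p["clean"], dtype=np.float64)
                      for pid, p in blob["patients"].items()},
        anomaly_labels={pid: np.asarray(p["anomaly"], dtype=bool)
                        for pid, p in blob["patients"].items()},
        condition={pid: p["condition"] for pid, p in blob["patients"].items()},
        kernels={lab: InterventionKernel(eta=k["eta"], lam=k["lam"],
                                         direction=np.asarray(k["direction"]))
                 for lab, k in blob["kernels"].items()},
    )


def log_run(path: str, config: RunConfig, event: str, **extra) -> None:
    """Append a plain-text log line with timestamp, config hash and seed."""
    stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    libs = f"numpy={np.__version__} pandas={pd.__version__}"
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    with open(path, "a") as fh:
        fh.write(f"{stamp} event={event} config_hash={config.config_hash()} "
                 f"seed={config.seed} {libs} {kv}\n".rstrip() + "\n")
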