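"""Symbolic patient-trajectory representation and the typed cardiovascular graph.

A patient encounter is a time-indexed sequence of physiological state
vectors together with discrete clinical events and intervention actions.
The graph view places one node per record, typed ``state`` / ``event`` /
``action``, and connects nodes through (a) a temporal backbone between
consecutive state samples, (b) bidirected co-occurrence edges between any
two nodes closer than a window, and (c) directed causal edges instantiated
from a rule table of clinical priors, with weights decaying in the lag to
encode expected pharmacodynamic delays.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventRecord", "ActionRecord", "PatientTrajectory", "CausalPriorRule",
    "CausalPriorTable", "GraphNode", "GraphEdge", "CardioGraph",
    "build_graph", "filter_edges", "backbone_pairs",
]

_KIND_ORDER = {"state": 0, "event": 1, "action": 2}


@dataclass(frozen=True)
class EventRecord:
    """A timestamped clinical event with a feature vector and a type label."""

    time: float
    features: np.ndarray
    label: str

    def __post_init__(self):
        object.__setattr__(self, "features", np.asarray(self.features, dtype=np.float64))


@dataclass(frozen=True)
class ActionRecord:
    """A timestamped intervention action with a feature vector.

    ``label`` names the intervention type so causal-prior rules can match it;
    it is empty when the cohort does not distinguish intervention types.
    """

    time: float
    features: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "features", np.asarray(self.features, dtype=np.float64))


@dataclass
class PatientTrajectory:
    """One patient's multimodal record: states, events, actions on [0, T]."""

    patient_id: str
    timestamps: np.ndarray
    states: np.ndarray
    events: list[EventRecord] = field(default_factory=list)
    actions: list[ActionRecord] = field(default_factory=list)
    episode_duration: float | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.float64)
        if self.states.ndim != 2:
            self.states = self.states.reshape(len(self.timestamps), -1)
        if self.episode_duration is None:
            times = [self.timestamps.max(initial=0.0)]
            times += [e.time for e in self.events] + [a.time for a in self.actions]
            self.episode_duration = float(max(times))
        self.validate()

    @property
    def d(self) -> int:
        return self.states.shape[1]

    @property
    def n_steps(self) -> int:
        return len(self.timestamps)

    def validate(self) -> None:
        pid = self.patient_id
        if self.n_steps == 0:
            raise ValueError(f"patient {pid!r}: trajectory has no state samples")
        if self.states.shape[0] != self.n_steps:
            raise ValueError(f"patient {pid!r}: {self.states.shape[0]} states for "
                             f"{self.n_steps} timestamps")
        if self.states.shape[1] < 1:
            raise ValueError(f"patient {pid!r}: state dimension must be >= 1")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError(f"patient {pid!r}: timestamps must be strictly increasing")
        T = float(self.episode_duration)
        if self.timestamps[0] < 0 or self.timestamps[-1] > T:
            raise ValueError(f"patient {pid!r}: timestamps outside [0, {T}]")
        d_e = {e.features.shape[0] for e in self.events}
        if len(d_e) > 1:
            raise ValueError(f"patient {pid!r}: ragged event feature dimensions {d_e}")
        d_a = {a.features.shape[0] for a in self.actions}
        if len(d_a) > 1:
            raise ValueError(f"patient {pid!r}: ragged action feature dimensions {d_a}")
        for rec in list(self.events) + list(self.actions):
            if rec.time < 0 or rec.time > T:
                raise ValueError(f"patient {pid!r}: record at t={rec.time} outside [0, {T}]")


@dataclass(frozen=True)
class CausalPriorRule:
    """One clinical-prior rule: src pattern -> dst pattern within max_lag seconds."""

    src_kind: str
    src_label: str
    dst_kind: str
    dst_label: str
    max_lag: float
    weight: float = 1.0
    direction: str = "forward"   # "forward" or "both"

    def __post_init__(self):
        if self.max_lag <= 0:
            raise ValueError(f"rule {self}: max_lag must be > 0")
        if self.weight < 0:
            raise ValueError(f"rule {self}: weight must be >= 0")


@dataclass
class CausalPriorTable:
    rules: list[CausalPriorRule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class GraphNode:
    node_id: int
    kind: str               # state | event | action
    time: float
    payload_index: int      # row into trajectory.states or index into events/actions
    label: str = ""


@dataclass(frozen=True)
class GraphEdge:
    src: int
    dst: int
    weight: float
    provenance: str         # temporal | causal


@dataclass
class CardioGraph:
    """Typed directed graph over one trajectory (nodes sorted by time, kind)."""

    patient_id: str
    nodes: list[GraphNode]
    edges: list[GraphEdge]

    def __post_init__(self):
        self.node_index = {n.node_id: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def kind_counts(self) -> dict[str, int]:
        out = {"state": 0, "event": 0, "action": 0}
        for n in self.nodes:
            out[n.kind] += 1
        return out

    def in_neighbors(self, node_id: int) -> list[int]:
        """Sources of edges into ``node_id`` — the neighborhood used by attention."""
        return [e.src for e in self.edges if e.dst == node_id]

    def node_times(self) -> np.ndarray:
        return np.array([n.time for n in self.nodes], dtype=np.float64)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        src = np.array([e.src for e in self.edges], dtype=np.intp)
        dst = np.array([e.dst for e in self.edges], dtype=np.intp)
        return src, dst

    def undirected_support(self) -> set[tuple[int, int]]:
        return {(min(e.src, e.dst), max(e.src, e.dst)) for e in self.edges}


def _match(rule_kind: str, rule_pattern: str, node: GraphNode) -> bool:
    return node.kind == rule_kind and fnmatch.fnmatchcase(node.label, rule_pattern)


def build_graph(trajectory: PatientTrajectory, priors: CausalPriorTable | None = None,
                window: float = 10.0) -> CardioGraph:
    """Build the typed graph for one trajectory.

    Edges, in order of instantiation (duplicate directed pairs are kept once,
    with causal provenance overriding temporal since it carries rule info):

    1. bidirected temporal backbone between consecutive state nodes;
    2. bidirected temporal co-occurrence edges between any two nodes within
       ``window`` seconds of each other;
    3. directed causal edges for every prior rule matched within its lag,
       weighted ``rule.weight * exp(-dt / max_lag)``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    trajectory.validate()
    priors = priors or CausalPriorTable()

    records = [("state", i, float(t), "") for i, t in enumerate(trajectory.timestamps)]
    records += [("event", i, float(e.time), e.label) for i, e in enumerate(trajectory.events)]
    records += [("action", i, float(a.time), a.label) for i, a in enumerate(trajectory.actions)]
    # stable ordering: time, then kind, then input order
    records.sort(key=lambda r: (r[2], _KIND_ORDER[r[0]], r[1]))
    nodes = [GraphNode(node_id=i, kind=k, time=t, payload_index=j, label=lab)
             for i, (k, j, t, lab) in enumerate(records)]

    state_ids = [n.node_id for n in nodes if n.kind == "state"]

    edges: dict[tuple[int, int], GraphEdge] = {}

    def put(src: int, dst: int, weight: float, provenance: str) -> None:
        if src == dst:
            return
        key = (src, dst)
        if key in edges and not (provenance == "causal" and edges[key].provenance == "temporal"):
            return
        edges[key] = GraphEdge(src, dst, float(weight), provenance)

    for a, b in zip(state_ids[:-1], state_ids[1:]):
        put(a, b, 1.0, "temporal")
        put(b, a, 1.0, "temporal")

    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if v.time - u.time > window:
                break
            put(u.node_id, v.node_id, 1.0, "temporal")
            put(v.node_id, u.node_id, 1.0, "temporal")

    for rule in priors.rules:
        for u in nodes:
            if not _match(rule.src_kind, rule.src_label, u):
                continue
            for v in nodes:
                if v.node_id == u.node_id or not _match(rule.dst_kind, rule.dst_label, v):
                    continue
                dt = v.time - u.time
                if 0 < dt <= rule.max_lag:
                    put(u.node_id, v.node_id,
                        rule.weight * np.exp(-dt / rule.max_lag), "causal")
                elif rule.direction == "both" and 0 < -dt <= rule.max_lag:
                    put(u.node_id, v.node_id,
                        rule.weight * np.exp(dt / rule.max_lag), "causal")

    edge_list = [edges[k] for k in sorted(edges)]
    return CardioGraph(patient_id=trajectory.patient_id, nodes=nodes, edges=edge_list)


def backbone_pairs(graph: CardioGraph) -> set[tuple[int, int]]:
    """Directed pairs of the consecutive-state temporal backbone."""
    state_ids = [n.node_id for n in graph.nodes if n.kind == "state"]
    out: set[tuple[int, int]] = set()
    for a, b in zip(state_ids[:-1], state_ids[1:]):
        out.add((a, b))
        out.add((b, a))
    return out


def filter_edges(graph: CardioGraph, relevance: dict[tuple[int, int], float],
                 threshold: float) -> CardioGraph:
    """Keep edges whose relevance score is >= threshold.

    The consecutive-state backbone is never removed, so the graph stays
    connected in time. Every non-backbone edge must have a score.
    """
    backbone = backbone_pairs(graph)
    kept = []
    for e in graph.edges:
        key = (e.src, e.dst)
        if key in backbone:
            kept.append(e)
            continue
        if key not in relevance:
            raise ValueError(f"edge {key} has no relevance score")
        if relevance[key] >= threshold:
            kept.append(e)
    return CardioGraph(patient_id=graph.patient_id, nodes=list(graph.nodes), edges=kept)
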