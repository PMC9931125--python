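"""Protein network container and the signal-propagation engine.

The model treats the directed protein–protein interaction network like a
multilayer perceptron laid over the graph: proteins are the units, links
carry a weight in [-1, 1], and an activation/inhibition signal injected
at the stimulus proteins (drug targets, clamped at ±1) is propagated
synchronously for a fixed number of steps.  Each non-clamped node's next
activity is the saturating-linear clamp to [-1, 1] of the weighted sum
of its incoming signals.  Basal-state proteins start at their disease
sign but are free to change, so a drug can modulate them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .characterization import ValidationError

logger = logging.getLogger(__name__)

#: SIF relation keywords carrying a prior sign for the edge weight
SIF_RELATION_SIGNS = {"act": +1, "activates": +1, "inh": -1, "inhibits": -1}

DEFAULT_STEPS = 3


@dataclass(frozen=True)
class ProteinNetwork:
    """Directed protein network with optional per-edge prior signs.

    ``prior_sign`` maps an edge to +1/-1 when the direction of effect
    (activation/inhibition) is known a priori; such edges have their
    sampled weight constrained to that sign during training.  Edges
    without an entry are unconstrained.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    prior_sign: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        seen: set[tuple[str, str]] = set()
        for s, t in self.edges:
            if s == t:
                raise ValidationError(f"self-loop {s!r} not allowed")
            if s not in node_set or t not in node_set:
                raise ValidationError(f"edge ({s!r}, {t!r}) references unknown node")
            if (s, t) in seen:
                raise ValidationError(f"duplicate edge ({s!r}, {t!r})")
            seen.add((s, t))
        for e, sign in self.prior_sign.items():
            if e not in seen:
                raise ValidationError(f"prior sign on unknown edge {e!r}")
            if sign not in (+1, -1):
                raise ValidationError(f"prior sign for {e!r} must be ±1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.nodes)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(source_idx, target_idx) integer arrays aligned with ``edges``."""
        idx = self.node_index()
        src = np.fromiter((idx[s] for s, _ in self.edges), dtype=np.intp, count=self.n_edges)
        dst = np.fromiter((idx[t] for _, t in self.edges), dtype=np.intp, count=self.n_edges)
        return src, dst

    def prior_sign_array(self) -> np.ndarray:
        """Per-edge prior sign (+1/-1) or 0 where unconstrained."""
        return np.array([self.prior_sign.get(e, 0) for e in self.edges], dtype=np.int8)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, prior_sign=self.prior_sign.get(e, 0))
        return g


def network_from_edges(
    edges: Iterable[tuple[str, str]],
    prior_sign: Mapping[tuple[str, str], int] | None = None,
    extra_nodes: Iterable[str] = (),
) -> ProteinNetwork:
    """Build a network from an edge iterable, dropping self-loops/duplicates."""
    kept: list[tuple[str, str]] = []
    nodes: dict[str, None] = {}
    seen: set[tuple[str, str]] = set()
    for s, t in edges:
        if s == t:
            logger.warning("dropping self-loop on %s", s)
            continue
        if (s, t) in seen:
            logger.warning("dropping duplicate edge %s -> %s", s, t)
            continue
        seen.add((s, t))
        kept.append((s, t))
        nodes.setdefault(s)
        nodes.setdefault(t)
    for n in extra_nodes:
        nodes.setdefault(n)
    priors = {e: s for e, s in (prior_sign or {}).items() if e in seen}
    return ProteinNetwork(tuple(nodes), tuple(kept), priors)


def load_network(path: str | Path) -> ProteinNetwork:
    """Load a network from SIF or a 2/3-column TSV edge list.

    SIF lines are ``source<TAB>relation<TAB>target``; relations ``act``/
    ``inh`` (or ``activates``/``inhibits``) set the edge's prior sign,
    any other relation leaves it unconstrained.  A headerless 2-column
    TSV is read as (source, target); a 3-column TSV as SIF.
    Self-loops and duplicate edges are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: list[tuple[str, str]] = []
    priors: dict[tuple[str, str], int] = {}
    n_lines = 0
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split("\t")
        if len(parts) == 2:
            s, t = parts
        elif len(parts) == 3:
            s, rel, t = parts
            sign = SIF_RELATION_SIGNS.get(rel.lower())
            if sign is not None:
                priors[(s, t)] = sign
        else:
            raise ValidationError(f"{path}: malformed line {line!r}")
        edges.append((s, t))
    if n_lines == 0:
        raise ValidationError(f"{path}: empty network file")
    net = network_from_edges(edges, priors)
    logger.info("loaded network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def write_network(net: ProteinNetwork, path: str | Path) -> None:
    """Write a network as SIF; prior signs map to act/inh, unknown to ``int``."""
    rel = {+1: "act", -1: "inh", 0: "int"}
    lines = [
        f"{s}\t{rel[net.prior_sign.get((s, t), 0)]}\t{t}"
        for s, t in net.edges
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# weights, stimulus, activity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolutionWeights:
    """One complete assignment of link weights, with its training accuracy."""

    weights: np.ndarray  # aligned with ProteinNetwork.edges
    accuracy: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1:
            raise ValidationError("weights must be a 1-D array aligned with network edges")
        if np.any(np.abs(w) > 1.0 + 1e-12):
            raise ValidationError("edge weights must lie in [-1, 1]")


@dataclass(frozen=True)
class Stimulus:
    """Clamped (held every step) and basal (initial-only) protein values.

    A protein appearing in both mappings keeps its clamped (drug) value;
    the basal entry is dropped with a warning.
    """

    clamped: Mapping[str, int] = field(default_factory=dict)
    basal: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in (("clamped", self.clamped), ("basal", self.basal)):
            for p, v in mapping.items():
                if v not in (+1, -1):
                    raise ValidationError(f"{name} value for {p!r} must be ±1")
        overlap = set(self.clamped) & set(self.basal)
        if overlap:
            logger.warning(
                "proteins %s are both clamped and basal; clamped value wins",
                sorted(overlap),
            )
            basal = {p: v for p, v in self.basal.items() if p not in overlap}
            object.__setattr__(self, "basal", basal)

    def with_basal(self, basal: Mapping[str, int]) -> "Stimulus":
        return Stimulus(dict(self.clamped), dict(basal))


@dataclass(frozen=True)
class ActivityProfile:
    """Predicted protein activity in [-1, 1] for every network node."""

    activity: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [p for p, a in self.activity.items() if abs(a) > 1.0 + 1e-9]
        if bad:
            raise ValidationError(f"activities outside [-1, 1] for {bad[:5]}")

    def __getitem__(self, protein: str) -> float:
        return self.activity[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.activity

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.activity), name="activity")


def write_profile(profile: ActivityProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {"protein": list(profile.activity), "activity": list(profile.activity.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def load_profile(path: str | Path) -> ActivityProfile:
    df = pd.read_csv(path, sep="\t")
    return ActivityProfile(dict(zip(df["protein"].astype(str), df["activity"].astype(float))))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def _stimulus_indices(
    net: ProteinNetwork, stim: Stimulus
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    idx = net.node_index()
    missing = [p for p in (*stim.clamped, *stim.basal) if p not in idx]
    if missing:
        raise ValidationError(f"stimulus proteins absent from network: {sorted(missing)}")
    c_idx = np.array([idx[p] for p in stim.clamped], dtype=np.intp)
    c_val = np.array(list(stim.clamped.values()), dtype=float)
    b_idx = np.array([idx[p] for p in stim.basal], dtype=np.intp)
    b_val = np.array(list(stim.basal.values()), dtype=float)
    return c_idx, c_val, b_idx, b_val


def weight_matrix(net: ProteinNetwork, w: SolutionWeights) -> np.ndarray:
    """Dense (n, n) matrix with W[target, source] = weight of source->target."""
    if len(w.weights) != net.n_edges:
        raise ValidationError(
            f"solution has {len(w.weights)} weights for {net.n_edges} edges"
        )
    src, dst = net.edge_arrays()
    mat = np.zeros((net.n_nodes, net.n_nodes))
    mat[dst, src] = w.weights
    return mat


def propagate(
    net: ProteinNetwork,
    w: SolutionWeights,
    stim: Stimulus,
    steps: int = DEFAULT_STEPS,
) -> ActivityProfile:
    """Propagate a stimulus through the weighted network.

    Synchronous update for ``steps`` iterations: every non-clamped node's
    next activity is ``clip(sum_in(weight * source_activity), -1, 1)``;
    clamped nodes hold their stimulus value at every step; basal nodes
    start at their basal value but update freely; all other nodes start
    at zero.  Returns the final state for every node.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    mat = weight_matrix(net, w)
    c_idx, c_val, b_idx, b_val = _stimulus_indices(net, stim)
    x = np.zeros(net.n_nodes)
    x[b_idx] = b_val
    x[c_idx] = c_val
    for _ in range(steps):
        x = np.clip(mat @ x, -1.0, 1.0)
        x[c_idx] = c_val
    return ActivityProfile(dict(zip(net.nodes, x.tolist())))


def ensemble_profile(
    net: ProteinNetwork,
    ensemble: Sequence[SolutionWeights],
    stim: Stimulus,
    steps: int = DEFAULT_STEPS,
) -> ActivityProfile:
    """Per-protein arithmetic mean of ``propagate`` over all solutions."""
    if not ensemble:
        raise ValidationError("ensemble must contain at least one solution")
    total = np.zeros(net.n_nodes)
    for sol in ensemble:
        profile = propagate(net, sol, stim, steps)
        total += np.fromiter(
            (profile[p] for p in net.nodes), dtype=float, count=net.n_nodes
        )
    mean = total / len(ensemble)
    return ActivityProfile(dict(zip(net.nodes, mean.tolist())))
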