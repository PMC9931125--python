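"""Motive-level impact measures, combination synergy, and MoA path extraction.

An effector is *reversed* when its ensemble-mean predicted activity has
the opposite sign to its disease sign with magnitude >= 0.1, and
*anti-reversed* when pushed further in the disease direction at the same
magnitude.  Per motive the impact is summarized by the reversed and
anti-reversed counts (#Eff, #-Eff), the fraction of the motive reversed,
and two intensity scores:

    T = mean over effectors of (-disease_sign * activity)
    W = ((1 + #Eff) / (1 + #-Eff)) * (#Eff / BED_p) + T

where BED_p is the total number of effectors in the motive.  T is the
mean signed reversion strength (positive = net reversion); W weights the
count of correctly vs incorrectly moved effectors against the motive
size and adds the signal strength.

A drug combination is *synergistic* on a motive when its W strictly
exceeds both single-drug W values.  The mechanism-of-action subgraph is
the set of high-support stimulus->effector paths across the ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .characterization import (
    DiseaseCharacterization,
    DrugProfile,
    Motive,
    ValidationError,
)
from .network import ActivityProfile, ProteinNetwork, SolutionWeights, Stimulus

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.1
DEFAULT_MODULATION_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# reversal and per-motive impact
# ---------------------------------------------------------------------------


def is_reversed(activity: float, disease_sign: int, epsilon: float = DEFAULT_EPSILON) -> bool:
    """True iff the activity opposes the disease sign with magnitude >= ε.

    The boundary is inclusive: |activity| exactly ε counts.  Activity 0
    is neither reversed nor anti-reversed.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if activity == 0:
        return False
    return abs(activity) >= epsilon and (activity > 0) == (disease_sign < 0)


def is_anti_reversed(activity: float, disease_sign: int, epsilon: float = DEFAULT_EPSILON) -> bool:
    """True iff the activity reinforces the disease sign with magnitude >= ε."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if activity == 0:
        return False
    return abs(activity) >= epsilon and (activity > 0) == (disease_sign > 0)


def t_signal(profile: ActivityProfile, motive: Motive) -> float:
    """Mean signed reversion strength over the motive's effectors.

    Positive values mean net reversion of the disease state; the measure
    is odd in the profile and bounded in [-1, 1].
    """
    if motive.bed_p == 0:
        raise ValidationError(f"motive {motive.name!r} has no effectors")
    return float(
        np.mean([-e.disease_sign * profile[e.protein] for e in motive.effectors])
    )


def w_signal(n_eff: int, n_anti: int, bed_p: int, t: float) -> float:
    """Composite intensity: ((1+#Eff)/(1+#-Eff)) * (#Eff/BED_p) + T."""
    if bed_p < 1:
        raise ValidationError("bed_p must be >= 1")
    if n_eff < 0 or n_anti < 0 or n_eff + n_anti > bed_p:
        raise ValidationError("need 0 <= n_eff + n_anti <= bed_p")
    return ((1 + n_eff) / (1 + n_anti)) * (n_eff / bed_p) + t


@dataclass(frozen=True)
class MotiveImpact:
    """Per-motive summary of a drug's (or combination's) predicted effect."""

    motive: str
    n_eff: int
    n_anti: int
    bed_p: int
    t_signal: float
    w_signal: float

    @property
    def pct_reversed(self) -> float:
        return 100.0 * self.n_eff / self.bed_p


def motive_impact(
    profile: ActivityProfile,
    motive: Motive,
    epsilon: float = DEFAULT_EPSILON,
) -> MotiveImpact:
    """Count reversed / anti-reversed effectors and compute T and W."""
    if motive.bed_p == 0:
        raise ValidationError(f"motive {motive.name!r} has no effectors")
    missing = [e.protein for e in motive.effectors if e.protein not in profile]
    if missing:
        raise ValidationError(f"profile lacks effectors {missing[:5]}")
    n_eff = sum(
        is_reversed(profile[e.protein], e.disease_sign, epsilon) for e in motive.effectors
    )
    n_anti = sum(
        is_anti_reversed(profile[e.protein], e.disease_sign, epsilon)
        for e in motive.effectors
    )
    t = t_signal(profile, motive)
    return MotiveImpact(
        motive.name, n_eff, n_anti, motive.bed_p, t, w_signal(n_eff, n_anti, motive.bed_p, t)
    )


def impact_table(
    profiles: Mapping[str, ActivityProfile],
    char: DiseaseCharacterization,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Impact report: one row per (treatment, motive)."""
    rows = []
    for treatment, profile in profiles.items():
        for motive in char.motives:
            imp = motive_impact(profile, motive, epsilon)
            rows.append(
                {
                    "treatment": treatment,
                    "motive": imp.motive,
                    "n_eff": imp.n_eff,
                    "n_anti": imp.n_anti,
                    "bed_p": imp.bed_p,
                    "pct_reversed": imp.pct_reversed,
                    "t_signal": imp.t_signal,
                    "w_signal": imp.w_signal,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# combinations and synergy
# ---------------------------------------------------------------------------


def combination_stimulus(drug_a: DrugProfile, drug_b: DrugProfile) -> Stimulus:
    """Joint stimulus clamping the union of both drugs' target values.

    Shared targets must agree in sign; a conflict is an error because a
    protein cannot be clamped both up and down.
    """
    a, b = drug_a.target_signs, drug_b.target_signs
    conflicts = [p for p in set(a) & set(b) if a[p] != b[p]]
    if conflicts:
        raise ValidationError(
            f"drugs {drug_a.name!r} and {drug_b.name!r} clamp {sorted(conflicts)} "
            "with conflicting signs"
        )
    return Stimulus(clamped={**a, **b})


def drug_stimulus(drug: DrugProfile) -> Stimulus:
    return Stimulus(clamped=drug.target_signs)


@dataclass(frozen=True)
class SynergyAssessment:
    """Comparison of single-drug and combination W-Signals on a motive."""

    w_a: float
    w_b: float
    w_combination: float

    @property
    def synergistic(self) -> bool:
        return self.w_combination > max(self.w_a, self.w_b)

    @property
    def label(self) -> str:
        return "synergistic" if self.synergistic else "additive-or-sub-additive"


def assess_synergy(w_a: float, w_b: float, w_ab: float) -> SynergyAssessment:
    """Synergistic iff the combination W strictly exceeds both singles."""
    return SynergyAssessment(w_a, w_b, w_ab)


# ---------------------------------------------------------------------------
# modulation classification (heatmap semantics)
# ---------------------------------------------------------------------------


def modulation_class(
    mean_a: float,
    mean_b: float,
    threshold: float = DEFAULT_MODULATION_THRESHOLD,
) -> str:
    """Which drug(s) modulate a protein, at a shared |activity| threshold.

    ``both`` when both means pass the threshold and differ by less than
    it; a single drug when only it passes, or when the means differ by
    at least the threshold and that drug's mean is the strictly larger
    in magnitude; ``neither`` otherwise (including the exact-tie case
    where neither magnitude is larger).
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    a_mod, b_mod = abs(mean_a) >= threshold, abs(mean_b) >= threshold
    differ = abs(mean_a - mean_b) >= threshold
    if a_mod and b_mod and not differ:
        return "both"
    if a_mod and (not b_mod or (differ and abs(mean_a) > abs(mean_b))):
        return "drug_a"
    if b_mod and (not a_mod or (differ and abs(mean_b) > abs(mean_a))):
        return "drug_b"
    return "neither"


def effector_heatmap(
    profile_a: ActivityProfile,
    profile_b: ActivityProfile,
    char: DiseaseCharacterization,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
    threshold: float = DEFAULT_MODULATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-effector table: mean activity per drug, disease sign, motive
    memberships and modulation class — the data behind the effector heatmap."""
    membership: dict[str, list[str]] = {}
    signs: dict[str, int] = {}
    for m in char.motives:
        for e in m.effectors:
            membership.setdefault(e.protein, []).append(m.name)
            signs[e.protein] = e.disease_sign
    rows = []
    for protein in sorted(membership):
        a, b = profile_a[protein], profile_b[protein]
        cls = modulation_class(a, b, threshold)
        label = {"drug_a": drug_a, "drug_b": drug_b}.get(cls, cls)
        rows.append(
            {
                "protein": protein,
                f"activity_{drug_a}": a,
                f"activity_{drug_b}": b,
                "disease_sign": signs[protein],
                "motives": ";".join(membership[protein]),
                "modulated_by": label,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MoA path extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoaSubgraph:
    """High-support stimulus->effector paths across the ensemble.

    ``support`` of an edge is the fraction of solutions in which the
    edge lies on at least one all-strong path (every edge |weight| >= ε)
    from a stimulus protein to an effector.  ``paths`` are the retained
    top-k node sequences, best first.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    support: Mapping[tuple[str, str], float]
    paths: tuple[tuple[str, ...], ...]

    @property
    def is_empty(self) -> bool:
        return not self.edges


def _strong_paths(
    adjacency: Mapping[str, list[str]],
    sources: Iterable[str],
    sinks: set[str],
    max_len: int,
) -> set[tuple[str, ...]]:
    """Simple directed paths (<= max_len edges) from sources into sinks."""
    found: set[tuple[str, ...]] = set()

    def walk(path: list[str]) -> None:
        node = path[-1]
        if len(path) > 1 and node in sinks:
            found.add(tuple(path))
        if len(path) > max_len:
            return
        for nxt in adjacency.get(node, ()):
            if nxt not in path:
                walk(path + [nxt])

    for s in sources:
        walk([s])
    return found


def extract_moa(
    net: ProteinNetwork,
    ensemble: Sequence[SolutionWeights],
    stimulus_proteins: Iterable[str],
    effector_proteins: Iterable[str],
    k: int = 5,
    epsilon: float = DEFAULT_EPSILON,
    max_len: int = 3,
) -> MoaSubgraph:
    """Extract the k highest-support stimulus->effector paths.

    Per solution, the qualifying paths are the simple directed paths of
    at most ``max_len`` edges from any stimulus protein to any effector
    whose every edge carries |weight| >= ε.  An edge's support is the
    fraction of solutions where it lies on >= 1 qualifying path.  Paths
    are scored by the minimum edge support along them, ties broken
    lexicographically by node sequence; the union subgraph of the top k
    is returned.  With no qualifying path anywhere, the result is empty.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not ensemble:
        raise ValidationError("ensemble must be non-empty")
    sources = [p for p in stimulus_proteins]
    sinks = set(effector_proteins)
    edge_counts: dict[tuple[str, str], int] = {}
    all_paths: set[tuple[str, ...]] = set()
    for sol in ensemble:
        strong = np.abs(sol.weights) >= epsilon
        adjacency: dict[str, list[str]] = {}
        for (s, t), keep in zip(net.edges, strong):
            if keep:
                adjacency.setdefault(s, []).append(t)
        paths = _strong_paths(adjacency, sources, sinks, max_len)
        all_paths.update(paths)
        edges_here = {e for p in paths for e in zip(p, p[1:])}
        for e in edges_here:
            edge_counts[e] = edge_counts.get(e, 0) + 1
    if not all_paths:
        logger.warning("no stimulus->effector path qualifies at epsilon=%g", epsilon)
        return MoaSubgraph((), (), {}, ())
    support = {e: c / len(ensemble) for e, c in edge_counts.items()}
    scored = sorted(
        all_paths,
        key=lambda p: (-min(support[e] for e in zip(p, p[1:])), p),
    )
    top = tuple(scored[:k])
    edges = tuple(sorted({e for p in top for e in zip(p, p[1:])}))
    nodes = tuple(sorted({n for p in top for n in p}))
    return MoaSubgraph(nodes, edges, {e: support[e] for e in edges}, top)


def write_moa(moa: MoaSubgraph, net: ProteinNetwork, prefix: str | Path) -> None:
    """Write the MoA subgraph as SIF plus a TSV of edge supports."""
    prefix = Path(prefix)
    rel = {+1: "act", -1: "inh", 0: "int"}
    sif_lines = [
        f"{s}\t{rel[net.prior_sign.get((s, t), 0)]}\t{t}" for s, t in moa.edges
    ]
    prefix.with_suffix(".sif").write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""))
    df = pd.DataFrame(
        {
            "source": [s for s, _ in moa.edges],
            "target": [t for _, t in moa.edges],
            "support": [moa.support[e] for e in moa.edges],
        }
    )
    df.to_csv(prefix.with_suffix(".supports.tsv"), sep="\t", index=False)
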