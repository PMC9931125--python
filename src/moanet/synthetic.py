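"""Synthetic fixtures with planted, verifiable drug mechanisms.

Every pipeline stage needs inputs — a protein network, a disease
characterization, drug profiles, a truth table and annotation
collections — that are internally consistent and carry a known ground
truth.  This module generates all five from one seeded specification:

* a directed scale-free network (preferential attachment, edges
  oriented from newer to existing nodes, so signal flows toward hubs);
* a full *true* weight assignment whose signs become the network's
  edge priors (activation/inhibition annotations);
* drug targets chosen to maximize downstream coverage, and disease
  effectors picked among nodes the drugs verifiably revert when the
  true weights are propagated — disease signs are set opposite to the
  drug-induced signs, so each drug's planted effectors are reversed by
  construction (re-checked by propagation during generation);
* a truth table whose responses are read off true-weight propagation
  (hence perfectly compliant at zero noise), with distractor rules from
  random stimuli so that high accuracy is not attainable trivially;
* annotation terms planted on each drug's effector set plus random
  decoy terms.

The default scale mirrors the study object counts: 4 motives (3
response + 1 basal) over 70 effector rows with 66 unique proteins, 2
drugs with 2 activating / 1 inhibiting target, and a 20-rule table.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .characterization import (
    DiseaseCharacterization,
    DrugProfile,
    Effector,
    Motive,
    TruthTableRule,
    ValidationError,
    write_characterization,
    write_drug_profile,
    write_truth_table,
)
from .enrichment import AnnotationCollection, write_gmt
from .network import (
    ProteinNetwork,
    SolutionWeights,
    Stimulus,
    propagate,
    write_network,
)

logger = logging.getLogger(__name__)

DEFAULT_MOTIVE_NAMES = (
    "Inflammatory cytokine storm",
    "Lung epithelial damage",
    "Pulmonary fibrosis",
    "Pneumonia and shortness of breath",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded specification of a complete synthetic fixture.

    ``effectors_per_motive`` fixes the number of motives; when there are
    at least two motives the last one takes the *basal* role (the
    baseline patient state) and the rest are *response* motives.
    ``n_shared_effectors`` proteins are listed in two motives each, so
    the unique effector count is ``sum(effectors_per_motive) - n_shared``.
    ``noise`` is the probability that a truth-table response sign is
    flipped; ``min_signal`` is the true-propagation magnitude required
    of planted effectors, bioflags and rule responses (kept above the
    scoring threshold 0.1 so planted structure has margin).
    """

    n_nodes: int = 200
    m: int = 5
    effectors_per_motive: tuple[int, ...] = (17, 17, 18, 18)
    n_shared_effectors: int = 4
    motive_names: tuple[str, ...] | None = DEFAULT_MOTIVE_NAMES
    drug_names: tuple[str, ...] = ("DrugA", "DrugB")
    targets_per_drug: tuple[int, ...] = (2, 1)
    drug_effects: tuple[str, ...] = ("act", "inh")
    n_bioflags_per_drug: int = 3
    n_rules: int = 20
    n_terms: int = 15
    term_size_range: tuple[int, int] = (5, 40)
    noise: float = 0.0
    steps: int = 3
    min_signal: float = 0.2
    weight_magnitude_range: tuple[float, float] = (0.5, 1.0)
    topology: str = "scale_free"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < self.m + 1:
            raise ValidationError("n_nodes must exceed attachment parameter m")
        if not (0.0 <= self.noise < 0.5):
            raise ValidationError("noise must lie in [0, 0.5)")
        if min(self.effectors_per_motive) < 1 or self.n_rules < 1 or self.n_terms < 1:
            raise ValidationError("all counts must be >= 1")
        if len(self.targets_per_drug) != len(self.drug_names):
            raise ValidationError("targets_per_drug must match drug_names")
        if self.n_shared_effectors >= min(self.effectors_per_motive):
            raise ValidationError("n_shared_effectors must be below the smallest motive")
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ValidationError("topology must be scale_free or erdos_renyi")

    @property
    def n_motives(self) -> int:
        return len(self.effectors_per_motive)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_names)

    @property
    def n_unique_effectors(self) -> int:
        return sum(self.effectors_per_motive) - self.n_shared_effectors

    def names(self) -> tuple[str, ...]:
        if self.motive_names and len(self.motive_names) == self.n_motives:
            return self.motive_names
        return tuple(f"Motive {i + 1}" for i in range(self.n_motives))

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}

    @classmethod
    def from_dict(cls, data: Mapping) -> "FixtureSpec":
        coerced = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()
        }
        return cls(**coerced)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: the quantities recovery is tested against."""

    network: ProteinNetwork
    weights: SolutionWeights
    drugs: tuple[DrugProfile, ...]
    effector_signs: Mapping[str, int]
    planted_effectors: Mapping[str, frozenset[str]]  # drug -> effectors it reverses
    planted_paths: Mapping[str, tuple[tuple[str, ...], ...]]


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def generate_network(spec: FixtureSpec) -> ProteinNetwork:
    """Directed scale-free (or Erdős–Rényi) graph, deterministic per seed.

    Preferential-attachment edges are oriented from the newly attached
    node to the existing one, yielding an acyclic graph with
    ``m * (n_nodes - m)`` edges.
    """
    if spec.topology == "scale_free":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.m, seed=spec.seed)
    else:
        p = min(1.0, 2.0 * spec.m / (spec.n_nodes - 1))
        g = nx.gnp_random_graph(spec.n_nodes, p, seed=spec.seed)
    edges = sorted((max(u, v), min(u, v)) for u, v in g.edges())
    named = [(_node_name(s), _node_name(t)) for s, t in edges]
    return ProteinNetwork(
        tuple(_node_name(i) for i in range(spec.n_nodes)), tuple(named)
    )


def _descendants_within(g: nx.DiGraph, source: str, hops: int) -> set[str]:
    seen = {source}
    frontier = {source}
    for _ in range(hops):
        frontier = {t for s in frontier for t in g.successors(s)} - seen
        seen |= frontier
    return seen - {source}


def _true_weights(net: ProteinNetwork, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.weight_magnitude_range
    mag = rng.uniform(lo, hi, size=net.n_edges)
    sign = rng.choice([-1.0, 1.0], size=net.n_edges)
    return mag * sign


def _greedy_targets(g: nx.DiGraph, spec: FixtureSpec, hops: int) -> list[list[str]]:
    """Pick drug targets greedily maximizing new downstream coverage."""
    reach = {n: _descendants_within(g, n, hops) for n in g.nodes}
    covered: set[str] = set()
    chosen: set[str] = set()
    per_drug: list[list[str]] = []
    for count in spec.targets_per_drug:
        targets: list[str] = []
        for _ in range(count):
            best = max(
                (n for n in g.nodes if n not in chosen),
                key=lambda n: (len(reach[n] - covered - chosen), n),
            )
            targets.append(best)
            chosen.add(best)
            covered |= reach[best]
        per_drug.append(targets)
    return per_drug


def plant_ground_truth(
    net: ProteinNetwork, spec: FixtureSpec
) -> tuple[GroundTruth, DiseaseCharacterization, list[DrugProfile]]:
    """Assign true weights and plant drug-reverted disease effectors.

    Effectors are chosen among nodes that carry true-weight signal of
    magnitude >= ``min_signal`` from some drug's targets within
    ``steps`` hops; their disease signs are set opposite to the induced
    activity, and every selection is re-verified by propagating the
    drug stimulus over the final basal state, so the planted effector
    sets are reversed by construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    weights = _true_weights(net, spec, rng)
    priors = {e: int(np.sign(w)) for e, w in zip(net.edges, weights)}
    net = ProteinNetwork(net.nodes, net.edges, priors)
    sol = SolutionWeights(weights)
    g = net.to_networkx()

    per_drug_targets = _greedy_targets(g, spec, spec.steps)
    all_targets = {t for ts in per_drug_targets for t in ts}
    drug_stims = {
        name: {t: (+1 if eff == "act" else -1) for t in ts}
        for name, ts, eff in zip(spec.drug_names, per_drug_targets, spec.drug_effects)
    }

    # no-basal activity per drug: the training-time view of each drug
    base_act = {
        name: propagate(net, sol, Stimulus(clamped=stim), spec.steps)
        for name, stim in drug_stims.items()
    }

    def pool_entries() -> list[tuple[str, str, float]]:
        """(node, owner drug, |activity|), strongest signal first."""
        entries = []
        for node in net.nodes:
            if node in all_targets:
                continue
            best = max(
                ((name, base_act[name][node]) for name in spec.drug_names),
                key=lambda kv: abs(kv[1]),
            )
            if abs(best[1]) >= spec.min_signal:
                entries.append((node, best[0], best[1]))
        return sorted(entries, key=lambda e: (-abs(e[2]), e[0]))

    pool = pool_entries()
    needed = spec.n_unique_effectors + spec.n_drugs * spec.n_bioflags_per_drug
    if len(pool) < needed:
        raise ValidationError(
            f"only {len(pool)} nodes receive signal >= {spec.min_signal} from the "
            f"planted targets but {needed} are needed; use a larger or denser network"
        )

    owner = {node: drug for node, drug, _ in pool}
    induced = {node: act for node, _, act in pool}
    disease_sign = {node: -int(np.sign(act)) for node, _, act in pool}

    n_basal = spec.effectors_per_motive[-1] if spec.n_motives > 1 else 0
    # round-robin over owning drugs (strongest signal first within each) so
    # every drug ends up with planted effectors of its own
    by_drug = {name: [n for n, d, _ in pool if d == name] for name in spec.drug_names}
    ordered = []
    for group in itertools.zip_longest(*by_drug.values()):
        ordered.extend(p for p in group if p is not None)

    # choose the basal set, then verify every candidate effector under the
    # analysis-time propagation (basal state initialized); replace basal
    # members whose own reversal breaks, and re-verify.
    basal_set = ordered[:n_basal]
    for _ in range(10):
        basal_state = {p: disease_sign[p] for p in basal_set}
        analysis_act = {
            name: propagate(
                net, sol, Stimulus(clamped=stim, basal=dict(basal_state)), spec.steps
            )
            for name, stim in drug_stims.items()
        }

        def verified(node: str) -> bool:
            a = analysis_act[owner[node]][node]
            return abs(a) >= spec.min_signal and np.sign(a) == np.sign(induced[node])

        bad = [p for p in basal_set if not verified(p)]
        if not bad:
            break
        replacements = [p for p in ordered if p not in basal_set and verified(p)]
        if len(replacements) < len(bad):
            raise ValidationError("cannot stabilize basal motive; enlarge the network")
        basal_set = [p for p in basal_set if p not in bad] + replacements[: len(bad)]
    else:
        raise ValidationError("basal motive did not stabilize; enlarge the network")

    good = [p for p in ordered if verified(p)]
    response_pool = [p for p in good if p not in basal_set]
    n_response_unique = spec.n_unique_effectors - n_basal
    if len(response_pool) < n_response_unique + spec.n_drugs * spec.n_bioflags_per_drug:
        raise ValidationError(
            "not enough verified downstream nodes for the requested effector and "
            "bioflag counts; use a larger or denser network"
        )
    response_unique = response_pool[:n_response_unique]

    # distribute unique proteins over response motives, then duplicate
    # n_shared proteins of the first motive into the later ones
    names = spec.names()
    sizes = list(spec.effectors_per_motive)
    motive_lists: list[list[str]] = []
    cursor = 0
    n_resp_motives = spec.n_motives - (1 if n_basal else 0)
    share_counts = [0] * n_resp_motives
    for j in range(spec.n_shared_effectors):
        share_counts[1 + j % max(1, n_resp_motives - 1)] += 1
    for i in range(n_resp_motives):
        take = sizes[i] - share_counts[i]
        motive_lists.append(response_unique[cursor:cursor + take])
        cursor += take
    shared_iter = iter(response_unique[: spec.n_shared_effectors])
    for i in range(1, n_resp_motives):
        for _ in range(share_counts[i]):
            motive_lists[i] = motive_lists[i] + [next(shared_iter)]
    if n_basal:
        motive_lists.append(list(basal_set))

    motives = []
    for i, (name, members) in enumerate(zip(names, motive_lists)):
        role = "basal" if (n_basal and i == spec.n_motives - 1) else "response"
        motives.append(
            Motive(name, tuple(Effector(p, disease_sign[p]) for p in members), role)
        )
    char = DiseaseCharacterization(tuple(motives))

    all_effectors = {p for members in motive_lists for p in members}
    bioflag_pool = [p for p in response_pool[n_response_unique:] if p not in all_effectors]
    drugs = []
    for name, ts, eff in zip(spec.drug_names, per_drug_targets, spec.drug_effects):
        mine = [p for p in bioflag_pool if owner[p] == name][: spec.n_bioflags_per_drug]
        bioflag_pool = [p for p in bioflag_pool if p not in mine]
        if len(mine) < spec.n_bioflags_per_drug:
            logger.warning("drug %s: only %d bioflags available", name, len(mine))
        bioflags = tuple((p, int(np.sign(base_act[name][p]))) for p in mine)
        drugs.append(DrugProfile(name, tuple((t, eff) for t in ts), bioflags))

    planted = {
        name: frozenset(
            p for p in all_effectors
            if abs(analysis_act[name][p]) >= 0.1
            and np.sign(analysis_act[name][p]) == -disease_sign[p]
        )
        for name in spec.drug_names
    }
    paths: dict[str, tuple[tuple[str, ...], ...]] = {}
    for name, ts in zip(spec.drug_names, per_drug_targets):
        drug_paths = []
        for p in sorted(planted[name]):
            for t in ts:
                try:
                    sp = nx.shortest_path(g, t, p)
                except nx.NetworkXNoPath:
                    continue
                if len(sp) - 1 <= spec.steps:
                    drug_paths.append(tuple(sp))
                    break
        paths[name] = tuple(drug_paths)

    gt = GroundTruth(
        network=net,
        weights=sol,
        drugs=tuple(drugs),
        effector_signs={p: disease_sign[p] for p in all_effectors},
        planted_effectors=planted,
        planted_paths=paths,
    )
    return gt, char, drugs


def generate_truth_table(gt: GroundTruth, spec: FixtureSpec) -> list[TruthTableRule]:
    """Drug rules plus distractor rules, responses read off true propagation.

    Each drug rule pairs the drug's target stimulus with the expected
    reversed signs of its planted effectors.  Distractor rules pick
    random stimuli and record the true-weight response at nodes carrying
    |activity| >= ``min_signal``; they are satisfiable by the true
    weights but not by arbitrary ones.  Each response sign is then
    flipped independently with probability ``noise``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    net, sol = gt.network, gt.weights
    rules: list[TruthTableRule] = []
    for drug in gt.drugs:
        response = tuple(
            (p, -gt.effector_signs[p]) for p in sorted(gt.planted_effectors[drug.name])
        )
        if not response:
            raise ValidationError(f"drug {drug.name} has no planted effectors")
        rules.append(
            TruthTableRule(
                f"rule_{drug.name}",
                tuple(sorted(drug.target_signs.items())),
                response,
                "treats",
            )
        )
    n_distractors = max(0, spec.n_rules - len(rules))
    nodes = list(net.nodes)
    made = 0
    attempts = 0
    while made < n_distractors and attempts < 50 * max(1, n_distractors):
        attempts += 1
        k = int(rng.integers(1, 4))
        stim_nodes = [nodes[i] for i in rng.choice(len(nodes), size=k, replace=False)]
        stim = {p: int(rng.choice([-1, 1])) for p in stim_nodes}
        profile = propagate(net, sol, Stimulus(clamped=stim), spec.steps)
        responsive = [
            p for p in nodes
            if p not in stim and abs(profile[p]) >= spec.min_signal
        ]
        if not responsive:
            continue
        n_resp = int(rng.integers(2, 6))
        picked = [responsive[i] for i in rng.choice(
            len(responsive), size=min(n_resp, len(responsive)), replace=False)]
        response = tuple((p, int(np.sign(profile[p]))) for p in sorted(picked))
        rules.append(
            TruthTableRule(
                f"rule_d{made:03d}", tuple(sorted(stim.items())), response, "causes"
            )
        )
        made += 1
    if made < n_distractors:
        logger.warning("only %d/%d distractor rules generated", made, n_distractors)
    if spec.noise > 0:
        noisy = []
        for rule in rules:
            response = tuple(
                (p, -s if rng.random() < spec.noise else s) for p, s in rule.response
            )
            noisy.append(
                TruthTableRule(rule.rule_id, rule.stimulus, response, rule.relation)
            )
        rules = noisy
    return rules


def generate_annotations(
    net: ProteinNetwork, gt: GroundTruth, spec: FixtureSpec
) -> AnnotationCollection:
    """One planted term per drug's effector set plus random decoy terms.

    When the network is large enough, one oversized term (>= 500
    proteins) is included so the size-exclusion filter has work to do.
    """
    rng = np.random.default_rng(spec.seed + 3)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for drug in gt.drugs:
        members = gt.planted_effectors[drug.name]
        if members:
            terms[f"TRUE_{drug.name}"] = (f"planted effectors of {drug.name}", members)
    nodes = list(net.nodes)
    lo, hi = spec.term_size_range
    i = 0
    while len(terms) < spec.n_terms:
        size = int(rng.integers(lo, min(hi, len(nodes)) + 1))
        members = frozenset(nodes[j] for j in rng.choice(len(nodes), size=size, replace=False))
        terms[f"RAND_{i:03d}"] = (f"random term {i}", members)
        i += 1
    if len(nodes) >= 500:
        members = frozenset(nodes[j] for j in rng.choice(len(nodes), size=500, replace=False))
        terms["OVERSIZE"] = ("oversized unspecific term", members)
    return AnnotationCollection("SYN", terms)


# ---------------------------------------------------------------------------
# one-call fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    network: ProteinNetwork  # carries the true-sign edge priors
    ground_truth: GroundTruth
    characterization: DiseaseCharacterization
    drugs: tuple[DrugProfile, ...]
    rules: tuple[TruthTableRule, ...]
    annotations: AnnotationCollection


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    spec = spec or FixtureSpec()
    net = generate_network(spec)
    gt, char, drugs = plant_ground_truth(net, spec)
    rules = generate_truth_table(gt, spec)
    annotations = generate_annotations(gt.network, gt, spec)
    return Fixture(
        spec, gt.network, gt, char, tuple(drugs), tuple(rules), annotations
    )


def write_fixture(fix: Fixture, outdir: str | Path) -> None:
    """Write the complete fixture directory in the standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(fix.network, outdir / "network.sif")
    write_characterization(fix.characterization, outdir / "characterization.tsv")
    for drug in fix.drugs:
        write_drug_profile(drug, outdir / f"drug_{drug.name}.tsv")
    write_truth_table(list(fix.rules), outdir / "truth_table.tsv")
    write_gmt(fix.annotations, outdir / "annotations.gmt")
    gt = fix.ground_truth
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "weights": {
                    f"{s}->{t}": w
                    for (s, t), w in zip(gt.network.edges, gt.weights.weights.tolist())
                },
                "effector_signs": dict(gt.effector_signs),
                "planted_effectors": {
                    d: sorted(v) for d, v in gt.planted_effectors.items()
                },
                "planted_paths": {
                    d: [list(p) for p in v] for d, v in gt.planted_paths.items()
                },
            },
            indent=1,
        )
    )
    (outdir / "manifest.json").write_text(
        json.dumps({"seed": fix.spec.seed, "spec": fix.spec.to_dict()}, indent=1)
    )
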