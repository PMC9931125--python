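"""Truth-table training: sample weight solutions, filter by accuracy, build the ensemble.

The number of truth-table constraints is always far smaller than the
number of link weights, so the trained model is not a single optimum but
a *population* of compliant solutions.  Each solution is found by
simulated annealing over the edge weights; a solution's accuracy is the
fraction of truth-table rules it complies with under propagation, and
only solutions with accuracy strictly above the retention threshold
(default 0.9) enter the ensemble.  The ensemble's accuracy is the mean
of its members' accuracies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .characterization import DrugProfile, TruthTableRule, ValidationError
from .network import (
    ActivityProfile,
    ProteinNetwork,
    SolutionWeights,
    Stimulus,
    propagate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the sampling/retention procedure.

    ``compliance_fraction`` (f) and ``epsilon`` define the per-rule
    compliance predicate: strictly more than a fraction f of a rule's
    response proteins must show the expected sign with magnitude >= ε.
    The annealing schedule is geometric: temperature starts at
    ``t_initial`` and is multiplied by ``cooling`` every iteration.
    """

    retention_threshold: float = 0.9
    target_size: int = 250
    max_attempts: int = 1000
    n_iterations: int = 2000
    t_initial: float = 0.05
    cooling: float = 0.998
    steps: int = 3
    compliance_fraction: float = 0.5
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.retention_threshold < 1.0):
            raise ValidationError("retention_threshold must be in (0, 1)")
        if self.target_size < 1:
            raise ValidationError("target_size must be >= 1")
        if not (0.0 < self.compliance_fraction <= 1.0):
            raise ValidationError("compliance_fraction must be in (0, 1]")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.n_iterations < 0 or self.max_attempts < 1 or self.steps < 1:
            raise ValidationError("n_iterations >= 0, max_attempts >= 1, steps >= 1 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainingConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "retention_threshold": self.retention_threshold,
            "target_size": self.target_size,
            "max_attempts": self.max_attempts,
            "n_iterations": self.n_iterations,
            "t_initial": self.t_initial,
            "cooling": self.cooling,
            "steps": self.steps,
            "compliance_fraction": self.compliance_fraction,
            "epsilon": self.epsilon,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class Ensemble:
    """The retained population of weight solutions — the trained model."""

    solutions: tuple[SolutionWeights, ...]
    retention_threshold: float
    target_size: int
    seed: int

    def __post_init__(self) -> None:
        for s in self.solutions:
            if not s.accuracy > self.retention_threshold:
                raise ValidationError(
                    f"retained solution accuracy {s.accuracy:.3f} not above "
                    f"threshold {self.retention_threshold}"
                )

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([s.accuracy for s in self.solutions]))

    def __len__(self) -> int:
        return len(self.solutions)


# ---------------------------------------------------------------------------
# rule compliance
# ---------------------------------------------------------------------------


def effective_rules(
    rules: Sequence[TruthTableRule],
    drugs: Sequence[DrugProfile] = (),
) -> list[TruthTableRule]:
    """Append each drug's bioflags as extra response requirements of its rules.

    A rule belongs to a drug when its stimulus protein set equals the
    drug's target set; the bioflag (protein, sign) pairs then count in
    that rule's compliance fraction like any other response protein.
    """
    by_targets = {frozenset(d.target_signs.items()): d for d in drugs}
    out: list[TruthTableRule] = []
    for rule in rules:
        drug = by_targets.get(frozenset(rule.stimulus))
        if drug is not None and drug.bioflags:
            existing = {p for p, _ in rule.response}
            extra = tuple((p, s) for p, s in drug.bioflags if p not in existing)
            rule = replace(rule, response=rule.response + extra)
        out.append(rule)
    return out


def rule_complied(
    profile: ActivityProfile,
    rule: TruthTableRule,
    f: float = 0.5,
    epsilon: float = 0.1,
) -> bool:
    """True iff strictly more than a fraction ``f`` of the rule's response
    proteins show the expected sign with magnitude >= ``epsilon``."""
    if not rule.response:
        raise ValidationError(f"rule {rule.rule_id!r} has an empty response")
    hits = 0
    for protein, expected in rule.response:
        a = profile[protein]
        if abs(a) >= epsilon and (a > 0) == (expected > 0) and a != 0:
            hits += 1
    return hits / len(rule.response) > f


def solution_accuracy(
    net: ProteinNetwork,
    w: SolutionWeights,
    rules: Sequence[TruthTableRule],
    config: TrainingConfig | None = None,
    drugs: Sequence[DrugProfile] = (),
) -> float:
    """Fraction of truth-table rules the solution complies with.

    Each rule's stimulus is propagated (clamped at its signs, no basal
    state) and the per-rule compliance predicate evaluated on the result.
    """
    config = config or TrainingConfig()
    rules = effective_rules(rules, drugs)
    if not rules:
        raise ValidationError("at least one rule required")
    ok = 0
    for rule in rules:
        stim = Stimulus(clamped=dict(rule.stimulus))
        profile = propagate(net, w, stim, config.steps)
        if rule_complied(profile, rule, config.compliance_fraction, config.epsilon):
            ok += 1
    return ok / len(rules)


# ---------------------------------------------------------------------------
# fast vectorized evaluation used inside the annealing loop
# ---------------------------------------------------------------------------


class RuleEngine:
    """Evaluates solution accuracy for all rules at once.

    Precomputes index arrays so that one accuracy evaluation is a
    handful of dense matrix products: all rules' stimuli are propagated
    as columns of one state matrix.  Produces the same accuracies as
    :func:`solution_accuracy` (asserted in the test suite); the slower
    per-rule path remains the reference definition.
    """

    def __init__(
        self,
        net: ProteinNetwork,
        rules: Sequence[TruthTableRule],
        config: TrainingConfig,
        drugs: Sequence[DrugProfile] = (),
    ) -> None:
        self.net = net
        self.config = config
        self.rules = effective_rules(rules, drugs)
        if not self.rules:
            raise ValidationError("at least one rule required")
        idx = net.node_index()
        n, r = net.n_nodes, len(self.rules)
        self.src, self.dst = net.edge_arrays()
        self.x0 = np.zeros((n, r))
        clamp_rows, clamp_cols, clamp_vals = [], [], []
        resp_rows, resp_cols, resp_signs = [], [], []
        self._resp_len = np.zeros(r)
        for j, rule in enumerate(self.rules):
            for p, s in rule.stimulus:
                clamp_rows.append(idx[p])
                clamp_cols.append(j)
                clamp_vals.append(float(s))
            for p, s in rule.response:
                resp_rows.append(idx[p])
                resp_cols.append(j)
                resp_signs.append(float(s))
            self._resp_len[j] = len(rule.response)
        self.c_rows = np.array(clamp_rows, dtype=np.intp)
        self.c_cols = np.array(clamp_cols, dtype=np.intp)
        self.c_vals = np.array(clamp_vals)
        self.r_rows = np.array(resp_rows, dtype=np.intp)
        self.r_cols = np.array(resp_cols, dtype=np.intp)
        self.r_signs = np.array(resp_signs)
        self.x0[self.c_rows, self.c_cols] = self.c_vals
        self._mat = np.zeros((n, n))

    def set_weights(self, weights: np.ndarray) -> None:
        self._mat[self.dst, self.src] = weights

    def update_weight(self, edge_index: int, value: float) -> None:
        self._mat[self.dst[edge_index], self.src[edge_index]] = value

    def accuracy(self) -> float:
        x = self.x0.copy()
        for _ in range(self.config.steps):
            x = np.clip(self._mat @ x, -1.0, 1.0)
            x[self.c_rows, self.c_cols] = self.c_vals
        a = x[self.r_rows, self.r_cols]
        hit = (np.abs(a) >= self.config.epsilon) & (np.sign(a) == self.r_signs)
        hits_per_rule = np.bincount(self.r_cols, weights=hit, minlength=len(self.rules))
        complied = hits_per_rule / self._resp_len > self.config.compliance_fraction
        return float(np.mean(complied))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def random_weights(net: ProteinNetwork, rng: np.random.Generator) -> np.ndarray:
    """Random initial weights in [-1, 1], respecting edge prior signs."""
    w = rng.uniform(-1.0, 1.0, size=net.n_edges)
    prior = net.prior_sign_array()
    constrained = prior != 0
    w[constrained] = np.abs(w[constrained]) * prior[constrained]
    return w


def sample_solution(
    net: ProteinNetwork,
    rules: Sequence[TruthTableRule],
    config: TrainingConfig,
    seed: int,
    drugs: Sequence[DrugProfile] = (),
    engine: RuleEngine | None = None,
) -> SolutionWeights:
    """One simulated-annealing run over the edge weights.

    Proposal: redraw one edge weight uniformly within [-1, 1] (its sign
    constrained by the edge prior, if any); objective: truth-table
    accuracy; acceptance: Metropolis with geometric cooling.  Returns
    the best weights seen.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if engine is None:
        engine = RuleEngine(net, rules, config, drugs)
    prior = net.prior_sign_array()
    w = random_weights(net, rng)
    engine.set_weights(w)
    acc = engine.accuracy()
    best_w, best_acc = w.copy(), acc
    temp = config.t_initial
    for _ in range(config.n_iterations):
        j = int(rng.integers(net.n_edges))
        proposal = rng.uniform(-1.0, 1.0)
        if prior[j] != 0:
            proposal = abs(proposal) * prior[j]
        old = w[j]
        engine.update_weight(j, proposal)
        new_acc = engine.accuracy()
        delta = new_acc - acc
        if delta >= 0 or (temp > 0 and rng.random() < math.exp(delta / temp)):
            w[j] = proposal
            acc = new_acc
            if acc > best_acc:
                best_acc = acc
                best_w = w.copy()
        else:
            engine.update_weight(j, old)
        temp *= config.cooling
    return SolutionWeights(best_w, best_acc)


def build_ensemble(
    net: ProteinNetwork,
    rules: Sequence[TruthTableRule],
    config: TrainingConfig,
    drugs: Sequence[DrugProfile] = (),
) -> Ensemble:
    """Sample solutions until ``target_size`` pass the accuracy filter.

    Attempt ``k`` uses seed ``config.seed + k`` so partial re-runs are
    reproducible.  Solutions with accuracy strictly above the retention
    threshold are kept.  If ``max_attempts`` is exhausted first, a
    partial ensemble is returned with a warning; zero retained solutions
    is an error (advice: relax the threshold or lengthen the schedule).
    """
    engine = RuleEngine(net, rules, config, drugs)
    retained: list[SolutionWeights] = []
    attempts = 0
    while len(retained) < config.target_size and attempts < config.max_attempts:
        sol = sample_solution(net, rules, config, config.seed + attempts, drugs, engine)
        attempts += 1
        if sol.accuracy > config.retention_threshold:
            retained.append(sol)
    if not retained:
        raise ValidationError(
            f"no solution exceeded accuracy {config.retention_threshold} in "
            f"{attempts} attempts; relax retention_threshold or increase "
            "n_iterations/t_initial"
        )
    if len(retained) < config.target_size:
        logger.warning(
            "partial ensemble: %d/%d solutions after %d attempts",
            len(retained), config.target_size, attempts,
        )
    ens = Ensemble(tuple(retained), config.retention_threshold, config.target_size, config.seed)
    logger.info(
        "ensemble: %d solutions, mean accuracy %.3f (%d attempts)",
        len(ens), ens.mean_accuracy, attempts,
    )
    return ens


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_ensemble(ens: Ensemble, net: ProteinNetwork, outdir: str | Path) -> None:
    """Write per-solution accuracies and long-format edge weights as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acc = pd.DataFrame(
        {"solution_id": range(len(ens)), "accuracy": [s.accuracy for s in ens.solutions]}
    )
    acc.to_csv(outdir / "solution_accuracies.tsv", sep="\t", index=False)
    frames = []
    for i, sol in enumerate(ens.solutions):
        frames.append(
            pd.DataFrame(
                {
                    "solution_id": i,
                    "source": [s for s, _ in net.edges],
                    "target": [t for _, t in net.edges],
                    "weight": sol.weights,
                }
            )
        )
    pd.concat(frames).to_csv(outdir / "solution_weights.tsv", sep="\t", index=False)


def load_ensemble(
    net: ProteinNetwork,
    outdir: str | Path,
    retention_threshold: float = 0.9,
    target_size: int | None = None,
    seed: int = 0,
) -> Ensemble:
    outdir = Path(outdir)
    acc = pd.read_csv(outdir / "solution_accuracies.tsv", sep="\t")
    weights = pd.read_csv(outdir / "solution_weights.tsv", sep="\t")
    edge_order = {e: i for i, e in enumerate(net.edges)}
    solutions = []
    for sid, grp in weights.groupby("solution_id", sort=True):
        w = np.zeros(net.n_edges)
        for _, row in grp.iterrows():
            w[edge_order[(str(row["source"]), str(row["target"]))]] = row["weight"]
        a = float(acc.loc[acc["solution_id"] == sid, "accuracy"].iloc[0])
        solutions.append(SolutionWeights(w, a))
    return Ensemble(
        tuple(solutions), retention_threshold, target_size or len(solutions), seed
    )
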