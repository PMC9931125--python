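"""Disease and drug characterization: motives, effectors, drug profiles, truth table.

A disease is characterized as a set of *motives* — pathophysiological
processes, each defined by protein *effectors* carrying a disease sign
(+1 overactivated, -1 inhibited in the disease state).  Drugs are
characterized by their protein targets (activation/inhibition) and by
*bioflags*: proteins whose activity is known to change downstream of the
drug without being direct targets.  The *truth table* is the training
set: stimulus -> expected-response relationships (e.g. drug targets vs
the effectors of a condition the drug treats) that any valid weight
solution must comply with.

File dialects are tab-separated with a header; JSON files with the same
schema are accepted wherever a loader takes a path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MOTIVE_ROLES = ("response", "basal", "context")

#: effect keywords used in drug-profile files, mapped to stimulus signs
EFFECT_SIGNS = {"act": +1, "inh": -1}

TRUTH_RELATIONS = ("treats", "causes")


class ValidationError(ValueError):
    """Raised when an input file or object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Effector:
    """A protein altered in the disease, with its disease direction."""

    protein: str
    disease_sign: int

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValidationError("effector protein identifier must be non-empty")
        if self.disease_sign not in (+1, -1):
            raise ValidationError(
                f"disease sign for {self.protein!r} must be +1 or -1, "
                f"got {self.disease_sign!r}"
            )


@dataclass(frozen=True)
class Motive:
    """A pathophysiological process defined by signed protein effectors.

    ``role`` distinguishes *response* motives (model outputs scored
    against the drug effect), the *basal* motive (the patient's baseline
    state, used to initialize propagation), and *context* motives
    (carried along but neither clamped nor scored).
    """

    name: str
    effectors: tuple[Effector, ...]
    role: str = "response"

    def __post_init__(self) -> None:
        if self.role not in MOTIVE_ROLES:
            raise ValidationError(
                f"motive {self.name!r}: role must be one of {MOTIVE_ROLES}, got {self.role!r}"
            )
        proteins = [e.protein for e in self.effectors]
        if len(set(proteins)) != len(proteins):
            dupes = sorted({p for p in proteins if proteins.count(p) > 1})
            raise ValidationError(f"motive {self.name!r}: duplicate effectors {dupes}")

    @property
    def bed_p(self) -> int:
        """Total number of effectors in this motive (the score denominator)."""
        return len(self.effectors)

    @property
    def signs(self) -> dict[str, int]:
        return {e.protein: e.disease_sign for e in self.effectors}


@dataclass(frozen=True)
class DiseaseCharacterization:
    """The full disease data model: a list of motives."""

    motives: tuple[Motive, ...]

    def __post_init__(self) -> None:
        if not any(m.role == "response" for m in self.motives):
            raise ValidationError("characterization needs at least one response motive")
        for m in self.motives:
            if m.bed_p < 1:
                raise ValidationError(f"motive {m.name!r} has no effectors")
        names = [m.name for m in self.motives]
        if len(set(names)) != len(names):
            raise ValidationError("motive names must be unique")

    @property
    def response_motives(self) -> tuple[Motive, ...]:
        return tuple(m for m in self.motives if m.role == "response")

    @property
    def basal_motives(self) -> tuple[Motive, ...]:
        return tuple(m for m in self.motives if m.role == "basal")

    def basal_state(self) -> dict[str, int]:
        """Protein -> disease sign over all basal-motive effectors."""
        state: dict[str, int] = {}
        for m in self.basal_motives:
            state.update(m.signs)
        return state

    def motive(self, name: str) -> Motive:
        for m in self.motives:
            if m.name == name:
                return m
        raise KeyError(name)


def unique_effectors(char: DiseaseCharacterization) -> set[str]:
    """Deduplicated union of effector proteins over all motives.

    Proteins may appear in more than one motive; the count of this set
    is the number of non-duplicated effectors of the characterization.
    """
    out: set[str] = set()
    for m in char.motives:
        out.update(e.protein for e in m.effectors)
    return out


@dataclass(frozen=True)
class DrugProfile:
    """A drug's direct targets (with act/inh effect) and its bioflags."""

    name: str
    targets: tuple[tuple[str, str], ...]
    bioflags: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"drug {self.name!r}: at least one target required")
        proteins = [p for p, _ in self.targets]
        if len(set(proteins)) != len(proteins):
            raise ValidationError(f"drug {self.name!r}: duplicate target proteins")
        for p, eff in self.targets:
            if eff not in EFFECT_SIGNS:
                raise ValidationError(
                    f"drug {self.name!r}: unknown effect {eff!r} on {p!r} "
                    f"(expected one of {sorted(EFFECT_SIGNS)})"
                )
        for p, s in self.bioflags:
            if s not in (+1, -1):
                raise ValidationError(f"drug {self.name!r}: bioflag sign for {p!r} not ±1")
        overlap = set(proteins) & {p for p, _ in self.bioflags}
        if overlap:
            raise ValidationError(
                f"drug {self.name!r}: bioflags overlap targets: {sorted(overlap)}"
            )

    @property
    def target_signs(self) -> dict[str, int]:
        """Targets mapped to stimulus signs (act -> +1, inh -> -1)."""
        return {p: EFFECT_SIGNS[eff] for p, eff in self.targets}

    @property
    def bioflag_signs(self) -> dict[str, int]:
        return dict(self.bioflags)


@dataclass(frozen=True)
class TruthTableRule:
    """One training constraint: a stimulus and the response it must evoke.

    ``relation`` records whether the stimulus is known to *treat* (revert)
    or *cause* (induce) the response protein state; the expected response
    signs are stored already resolved, so propagation-time evaluation
    does not need to re-interpret the relation.
    """

    rule_id: str
    stimulus: tuple[tuple[str, int], ...]
    response: tuple[tuple[str, int], ...]
    relation: str = "treats"

    def __post_init__(self) -> None:
        if self.relation not in TRUTH_RELATIONS:
            raise ValidationError(
                f"rule {self.rule_id!r}: relation must be one of {TRUTH_RELATIONS}"
            )
        if not self.stimulus or not self.response:
            raise ValidationError(f"rule {self.rule_id!r}: stimulus and response must be non-empty")
        for side in (self.stimulus, self.response):
            for p, s in side:
                if s not in (+1, -1):
                    raise ValidationError(f"rule {self.rule_id!r}: sign for {p!r} not ±1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a TSV (or same-schema JSON records) file and check columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _parse_sign(raw: object, where: str) -> int:
    try:
        value = int(str(raw))
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: sign {raw!r} is not an integer") from None
    if value not in (+1, -1):
        raise ValidationError(f"{where}: sign must be +1 or -1, got {value}")
    return value


def load_characterization(path: str | Path) -> DiseaseCharacterization:
    """Load a disease characterization table.

    Expected columns: ``motive``, ``role``, ``protein``, ``sign`` — one
    row per (motive, protein).  Signs must be ±1 and a protein may not
    be listed twice within the same motive.
    """
    df = _read_table(path, ("motive", "role", "protein", "sign"))
    motives: list[Motive] = []
    for (name, role), grp in df.groupby(["motive", "role"], sort=False):
        seen: set[str] = set()
        effectors = []
        for idx, row in grp.iterrows():
            protein = str(row["protein"])
            if protein in seen:
                raise ValidationError(
                    f"{path} row {idx}: duplicate ({name!r}, {protein!r}) pair"
                )
            seen.add(protein)
            sign = _parse_sign(row["sign"], f"{path} row {idx}")
            effectors.append(Effector(protein, sign))
        motives.append(Motive(str(name), tuple(effectors), str(role)))
    char = DiseaseCharacterization(tuple(motives))
    logger.info(
        "loaded characterization: %d motives, %d rows, %d unique effectors",
        len(char.motives), len(df), len(unique_effectors(char)),
    )
    return char


def write_characterization(char: DiseaseCharacterization, path: str | Path) -> None:
    rows = [
        {"motive": m.name, "role": m.role, "protein": e.protein, "sign": e.disease_sign}
        for m in char.motives
        for e in m.effectors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_drug_profile(path: str | Path, name: str | None = None) -> DrugProfile:
    """Load a drug profile table with columns ``kind``, ``protein``, ``effect``.

    ``kind`` is ``target`` or ``bioflag``; ``effect`` is ``act`` or ``inh``.
    The drug name defaults to the file stem.
    """
    path = Path(path)
    df = _read_table(path, ("kind", "protein", "effect"))
    targets: list[tuple[str, str]] = []
    bioflags: list[tuple[str, int]] = []
    for idx, row in df.iterrows():
        kind, protein, effect = str(row["kind"]), str(row["protein"]), str(row["effect"])
        if effect not in EFFECT_SIGNS:
            raise ValidationError(f"{path} row {idx}: unknown effect {effect!r}")
        if kind == "target":
            targets.append((protein, effect))
        elif kind == "bioflag":
            bioflags.append((protein, EFFECT_SIGNS[effect]))
        else:
            raise ValidationError(f"{path} row {idx}: unknown kind {kind!r}")
    return DrugProfile(name or path.stem, tuple(targets), tuple(bioflags))


def write_drug_profile(drug: DrugProfile, path: str | Path) -> None:
    sign_effects = {+1: "act", -1: "inh"}
    rows = [{"kind": "target", "protein": p, "effect": e} for p, e in drug.targets]
    rows += [
        {"kind": "bioflag", "protein": p, "effect": sign_effects[s]}
        for p, s in drug.bioflags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_truth_table(
    path: str | Path,
    network_nodes: Iterable[str] | None = None,
) -> list[TruthTableRule]:
    """Load truth-table rules from a long-format table.

    Columns: ``rule_id``, ``relation``, ``side`` (stimulus|response),
    ``protein``, ``sign``.  When ``network_nodes`` is given, proteins
    absent from the network are dropped from each rule (with a warning);
    a rule whose stimulus or response becomes empty is dropped entirely.
    """
    df = _read_table(path, ("rule_id", "relation", "side", "protein", "sign"))
    if df.empty:
        raise ValidationError(f"{path}: empty truth table — training impossible")
    known = set(network_nodes) if network_nodes is not None else None
    rules: list[TruthTableRule] = []
    for rid, grp in df.groupby("rule_id", sort=False):
        sides: dict[str, list[tuple[str, int]]] = {"stimulus": [], "response": []}
        relation = str(grp["relation"].iloc[0])
        for idx, row in grp.iterrows():
            side = str(row["side"])
            if side not in sides:
                raise ValidationError(f"{path} row {idx}: unknown side {side!r}")
            protein = str(row["protein"])
            sign = _parse_sign(row["sign"], f"{path} row {idx}")
            if known is not None and protein not in known:
                logger.warning("rule %s: protein %s absent from network, dropped", rid, protein)
                continue
            sides[side].append((protein, sign))
        if not sides["stimulus"] or not sides["response"]:
            logger.warning("rule %s dropped: stimulus or response empty after filtering", rid)
            continue
        rules.append(
            TruthTableRule(str(rid), tuple(sides["stimulus"]), tuple(sides["response"]), relation)
        )
    if not rules:
        raise ValidationError(f"{path}: no usable rules after filtering")
    logger.info("loaded truth table: %d rules", len(rules))
    return rules


def write_truth_table(rules: Sequence[TruthTableRule], path: str | Path) -> None:
    rows = []
    for r in rules:
        for side_name, side in (("stimulus", r.stimulus), ("response", r.response)):
            for p, s in side:
                rows.append(
                    {"rule_id": r.rule_id, "relation": r.relation,
                     "side": side_name, "protein": p, "sign": s}
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
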