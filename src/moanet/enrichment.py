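"""Hypergeometric over-representation analysis of drug-modulated protein sets.

Proteins the models predict as upregulated (activity >= 0.1) and
downregulated (activity <= -0.1) are tested separately against each
annotation collection (GO-like, KEGG-like, ...).  Terms of 500 or more
proteins are excluded beforehand to filter unspecific results.  P-values
are upper-tail hypergeometric; each (direction x collection) family is
adjusted independently with Benjamini-Hochberg, significant at q < 0.05.
Terms significant in both directions are reported as *modulated*.

The universe is the closed world of the model: every protein in the
loaded network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .characterization import ValidationError
from .network import ActivityProfile

logger = logging.getLogger(__name__)

DEFAULT_ACTIVITY_THRESHOLD = 0.1
DEFAULT_MAX_TERM_SIZE = 500
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AnnotationCollection:
    """A named set of annotation terms (GMT semantics).

    ``terms`` maps a term identifier to its display name and protein
    set; ``source`` labels the database the collection emulates.
    """

    source: str
    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValidationError(f"term {tid!r} has an empty protein set")

    def sizes(self) -> dict[str, int]:
        return {tid: len(members) for tid, (_, members) in self.terms.items()}


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationCollection:
    """Read a GMT file: one term per line, ``id<TAB>name<TAB>genes...``."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: GMT line needs id, name and >=1 gene: {line!r}")
        tid, name, genes = parts[0], parts[1], parts[2:]
        if tid in terms:
            raise ValidationError(f"{path}: duplicate term identifier {tid!r}")
        terms[tid] = (name, frozenset(g for g in genes if g))
    return AnnotationCollection(source or path.stem, terms)


def write_gmt(coll: AnnotationCollection, path: str | Path) -> None:
    lines = [
        "\t".join([tid, name, *sorted(members)])
        for tid, (name, members) in coll.terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def split_up_down(
    profile: ActivityProfile, threshold: float = DEFAULT_ACTIVITY_THRESHOLD
) -> tuple[set[str], set[str]]:
    """Split a profile into upregulated (>= thr) and downregulated (<= -thr)
    protein sets; the boundary is inclusive and the sets are disjoint."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    up = {p for p, a in profile.activity.items() if a >= threshold}
    down = {p for p, a in profile.activity.items() if a <= -threshold}
    return up, down


def filter_collection(
    coll: AnnotationCollection, max_size: int = DEFAULT_MAX_TERM_SIZE
) -> AnnotationCollection:
    """Drop terms whose protein set has ``max_size`` or more members."""
    if max_size < 1:
        raise ValidationError("max_size must be >= 1")
    kept = {
        tid: entry for tid, entry in coll.terms.items() if len(entry[1]) < max_size
    }
    dropped = len(coll.terms) - len(kept)
    if dropped:
        logger.info("excluded %d terms of size >= %d from %s", dropped, max_size, coll.source)
    return AnnotationCollection(coll.source, kept)


def hypergeom_test(query: set[str], term: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric p-value for the query/term overlap.

    Drawing |query| proteins from the universe with |term| successes,
    returns P(X >= observed overlap).  An empty query gives p = 1.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not query <= universe or not term <= universe:
        raise ValidationError("query and term must be subsets of the universe")
    overlap = len(query & term)
    # sf(k-1) = P(X >= k); overlap 0 gives exactly 1
    return float(hypergeom.sf(overlap - 1, len(universe), len(term), len(query)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    direction: str  # "up" | "down"
    collection: str
    term_id: str
    term_name: str
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_value: float
    q_value: float
    significant: bool


def enrich(
    profile: ActivityProfile,
    collections: Sequence[AnnotationCollection],
    universe: Iterable[str],
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    max_size: int = DEFAULT_MAX_TERM_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Full enrichment of a profile's up and down sets.

    Each (direction x collection) family is tested and BH-adjusted
    independently.  An empty direction set yields no results for that
    direction.  Term proteins outside the universe are ignored.
    """
    universe = set(universe)
    up, down = split_up_down(profile, threshold)
    outside = (up | down) - universe
    if outside:
        raise ValidationError(f"profile proteins outside the universe: {sorted(outside)[:5]}")
    results: list[EnrichmentResult] = []
    for direction, query in (("up", up), ("down", down)):
        if not query:
            continue
        for coll in collections:
            filtered = filter_collection(coll, max_size)
            term_ids = sorted(filtered.terms)
            if not term_ids:
                continue
            pvals = []
            for tid in term_ids:
                members = filtered.terms[tid][1] & universe
                pvals.append(hypergeom_test(query, members, universe) if members else 1.0)
            qvals = bh_adjust(pvals)
            for tid, p, q in zip(term_ids, pvals, qvals):
                name, members = filtered.terms[tid]
                members = members & universe
                results.append(
                    EnrichmentResult(
                        direction=direction,
                        collection=coll.source,
                        term_id=tid,
                        term_name=name,
                        overlap=len(query & members),
                        query_size=len(query),
                        term_size=len(members),
                        universe_size=len(universe),
                        p_value=float(p),
                        q_value=float(q),
                        significant=bool(q < alpha),
                    )
                )
    return results


def modulated_terms(results: Sequence[EnrichmentResult]) -> set[tuple[str, str]]:
    """(collection, term_id) pairs significant in both directions."""
    sig = {"up": set(), "down": set()}
    for r in results:
        if r.significant:
            sig[r.direction].add((r.collection, r.term_id))
    return sig["up"] & sig["down"]


def results_table(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
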