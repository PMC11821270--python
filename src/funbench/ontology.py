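"""Ontology handling: OBO parsing, ancestor propagation, information accretion,
and EC-number hierarchy manipulation.

The central object is :class:`OntologyDAG`, a thin wrapper over a directed
acyclic graph whose edges point child -> parent (GO ``is_a`` style).  Term
specificity is quantified by *information accretion* Ia(v) = -log2 Pr(v |
parents(v)), estimated from a reference annotation corpus: a term that is
nearly always present whenever its parents are carries almost no information,
while a rarely-added child term is highly informative.  These weights feed the
information-accretion-weighted Jaccard similarity used for GO annotation sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "ECNumber",
    "parse_obo",
    "propagate",
    "compute_information_accretion",
    "truncate_ec",
]


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown terms."""


@dataclass
class OntologyDAG:
    """Directed acyclic ontology graph with child -> parent edges.

    Parameters
    ----------
    graph : networkx.DiGraph
        Edges run from child term to parent term.  Must be acyclic.
    namespaces : mapping, optional
        Optional per-term namespace tags (e.g. ``molecular_function``).
    """

    graph: nx.DiGraph
    namespaces: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(
                f"ontology graph contains a cycle through {cycle[0][0]!r}"
            )

    @property
    def terms(self) -> set:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set:
        """Terms with no parents."""
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def parents(self, term) -> set:
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term!r}")
        return set(self.graph.successors(term))

    def ancestors(self, term) -> set:
        """All ancestors of ``term`` (excluding the term itself)."""
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term!r}")
        return set(nx.descendants(self.graph, term))


def parse_obo(path, include_part_of: bool = False) -> OntologyDAG:
    """Parse an OBO flat file into an :class:`OntologyDAG`.

    Obsolete terms are excluded.  Edges are built from ``is_a`` relations;
    ``part_of`` relationships are included when ``include_part_of`` is set.

    Raises
    ------
    OntologyError
        If the resulting graph has a cycle.
    OSError
        If the file cannot be read.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    graph.add_nodes_from(multigraph.nodes)
    namespaces = {
        node: data["namespace"]
        for node, data in multigraph.nodes(data=True)
        if "namespace" in data
    }
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a" or (include_part_of and key == "part_of"):
            graph.add_edge(child, parent)
    return OntologyDAG(graph=graph, namespaces=namespaces)


def propagate(dag: OntologyDAG, terms: Iterable) -> frozenset:
    """Ancestor closure of ``terms`` with ontology roots removed.

    Roots are shared by every annotated protein and carry zero information
    accretion, so keeping them would only inflate similarity denominators.

    Raises
    ------
    OntologyError
        If any input term is absent from the ontology.
    """
    terms = set(terms)
    unknown = terms - dag.terms
    if unknown:
        raise OntologyError(f"unknown terms: {sorted(map(str, unknown))}")
    closure = set(terms)
    for t in terms:
        closure |= dag.ancestors(t)
    return frozenset(closure - dag.roots)


def compute_information_accretion(
    dag: OntologyDAG,
    corpus: Mapping[str, Iterable],
    alpha: float = 1.0,
) -> dict:
    """Estimate per-term information accretion (bits) from an annotation corpus.

    Ia(v) = -log2 Pr(v | parents(v)) with the conditional probability
    estimated as ``(n_v_and_parents + alpha) / (n_parents + alpha)`` over the
    corpus proteins.  Corpus sets are expected to be ancestor-propagated
    (roots may be omitted: every protein is taken to carry all roots
    implicitly, hence Ia(root) = 0).

    Parameters
    ----------
    corpus : mapping protein -> term set
        Propagated annotation sets.
    alpha : float
        Additive smoothing constant; ``alpha=0`` gives the raw ML estimate
        (and infinite Ia for terms never co-occurring with their parents).
    """
    if not corpus:
        raise OntologyError("empty corpus: cannot estimate information accretion")
    sets = {p: frozenset(s) for p, s in corpus.items()}
    roots = dag.roots
    ia: dict = {}
    for term in dag.terms:
        if term in roots:
            ia[term] = 0.0
            continue
        parents = dag.parents(term) - roots
        n_parents = sum(1 for s in sets.values() if parents <= s)
        n_with = sum(1 for s in sets.values() if parents <= s and term in s)
        num = n_with + alpha
        den = n_parents + alpha
        if num <= 0 or den <= 0:
            ia[term] = math.inf
        else:
            ia[term] = max(0.0, -math.log2(num / den))
    return ia


# ---------------------------------------------------------------------------
# EC numbers

_MISSING = {"-", "", "n", "?"}


@dataclass(frozen=True)
class ECNumber:
    """An Enzyme Commission number of up to four hierarchy positions.

    Missing positions (``-``) are stored as ``None``.  A missing position
    implies all deeper positions are missing.  An *incomplete* EC (one with a
    missing position inside its retained prefix) never compares equal to any
    EC, including itself — truncating ``1.2.-.-`` to level 3 must not match
    ``1.2.3``.
    """

    positions: tuple

    def __post_init__(self):
        seen_missing = False
        for p in self.positions:
            if p is None:
                seen_missing = True
            elif seen_missing:
                raise ValueError(
                    f"EC positions after a missing digit must be missing: {self.positions}"
                )

    @classmethod
    def parse(cls, text: str) -> "ECNumber":
        text = text.strip()
        if text.upper().startswith("EC"):
            text = text[2:].lstrip(":").strip()
        parts = text.split(".")
        if not 1 <= len(parts) <= 4 or parts[0].strip() in _MISSING:
            raise ValueError(f"malformed EC number: {text!r}")
        positions = []
        for raw in parts:
            raw = raw.strip()
            positions.append(None if raw in _MISSING else raw)
        return cls(tuple(positions))

    @property
    def is_complete(self) -> bool:
        return all(p is not None for p in self.positions)

    @property
    def level(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ECNumber):
            return NotImplemented
        if not (self.is_complete and other.is_complete):
            return False
        return self.positions == other.positions

    def __hash__(self) -> int:
        return hash(self.positions)

    def __str__(self) -> str:
        return ".".join("-" if p is None else p for p in self.positions)


def truncate_ec(ec: ECNumber | str, level: int) -> ECNumber:
    """Truncate an EC number to its first ``level`` positions (EC1..EC4).

    If any retained position is missing, the result is incomplete and will
    not compare equal to anything.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"EC level must be in 1..4, got {level}")
    if isinstance(ec, str):
        ec = ECNumber.parse(ec)
    positions = ec.positions[:level]
    if len(positions) < level:
        positions = positions + (None,) * (level - len(positions))
    return ECNumber(positions)
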