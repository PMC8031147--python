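"""Markov equivalence classes: member enumeration, patterns, validation.

An essential graph (CPDAG) is read here as an explicit set of mutually
Markov-equivalent DAGs — its *members* — with a summary partially directed
graph derived from them: an edge is drawn directed when every member orients
it the same way, undirected when both orientations occur.  The member set is
the source of truth; the summary is always derived, never authoritative.
This matters for background-knowledge-restricted classes, which may be a
strict subset of a full pattern: an edge that happens to be constantly
oriented across a restricted member set is rendered directed in the summary.

Enumeration is brute force over the 2^u orientations of the u undirected
edges, filtered by acyclicity and by preservation of the uncovered-collider
set.  At the graph sizes this package targets, brute force is both fast and
simple enough to double as its own correctness oracle; a hard limit on u
guards against accidental combinatorial blow-up.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from itertools import product

import networkx as nx

from .graphs import (
    DAG,
    GraphError,
    PDGraph,
    equivalence_key,
    skeleton,
    uncovered_colliders,
)

__all__ = [
    "LimitError",
    "EquivalenceClass",
    "consistent_extensions",
    "pattern_of",
    "mec_members",
    "make_class",
    "EssentialGraphDiagnostic",
    "validate_essential_graph",
    "DEFAULT_UNDIRECTED_LIMIT",
]

DEFAULT_UNDIRECTED_LIMIT = 20


class LimitError(RuntimeError):
    """An enumeration limit was exceeded (combinatorial blow-up guard)."""


@dataclass(frozen=True)
class EquivalenceClass:
    """A set of mutually Markov-equivalent DAGs plus its derived summary.

    Construct through :func:`make_class` (which validates mutual
    equivalence) or :func:`mec_members`.  ``members`` may be a strict subset
    of a full pattern, e.g. under background knowledge.
    """

    members: frozenset[DAG]
    summary: PDGraph

    @property
    def nodes(self) -> frozenset[str]:
        return self.summary.nodes

    @property
    def undirected_edges(self) -> tuple[tuple[str, str], ...]:
        """The summary's undirected edges, canonical order, sorted."""
        return tuple(sorted(self.summary.undirected))

    def members_sorted(self) -> tuple[DAG, ...]:
        """Members in a deterministic order (by sorted edge list)."""
        return tuple(sorted(self.members, key=lambda d: sorted(d.directed)))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members_sorted())

    def __contains__(self, d: object) -> bool:
        return d in self.members


def _summarize(members: Iterable[DAG]) -> PDGraph:
    members = list(members)
    directed, undirected = [], []
    for a, b in sorted(skeleton(members[0])):
        if all((a, b) in d.directed for d in members):
            directed.append((a, b))
        elif all((b, a) in d.directed for d in members):
            directed.append((b, a))
        else:
            undirected.append((a, b))
    return PDGraph(nodes=members[0].nodes, directed=directed, undirected=undirected)


def make_class(members: Iterable[DAG]) -> EquivalenceClass:
    """Wrap an explicit member set, validating mutual Markov equivalence.

    Raises :class:`GraphError` naming a violating pair if any two members
    differ in skeleton or uncovered colliders, or if node sets differ.
    """
    mlist = sorted(set(members), key=lambda d: sorted(d.directed))
    if not mlist:
        raise GraphError("an equivalence class needs at least one member DAG")
    first = mlist[0]
    key = equivalence_key(first)
    for d in mlist[1:]:
        if d.nodes != first.nodes:
            raise GraphError("members have different node sets")
        if equivalence_key(d) != key:
            raise GraphError(
                f"members are not Markov equivalent: {first!r} vs {d!r}"
            )
    return EquivalenceClass(members=frozenset(mlist), summary=_summarize(mlist))


def consistent_extensions(
    g: PDGraph, *, limit: int = DEFAULT_UNDIRECTED_LIMIT
) -> frozenset[DAG]:
    """All DAGs obtained by orienting g's undirected edges admissibly.

    An orientation is admissible when the resulting directed graph is
    acyclic and its uncovered-collider set equals the uncovered colliders
    already present among g's directed edges — no v-structure is created or
    destroyed.  Directed edges of g are kept fixed.

    Raises
    ------
    LimitError
        If g has more than ``limit`` undirected edges.
    GraphError
        If g's directed edges already contain a cycle.
    """
    und = sorted(g.undirected)
    if len(und) > limit:
        raise LimitError(
            f"{len(und)} undirected edges exceeds the enumeration limit {limit}"
        )
    if not nx.is_directed_acyclic_graph(g.to_digraph()):
        raise GraphError("the directed edges of the input already contain a cycle")
    base_colliders = uncovered_colliders(g)
    fixed = sorted(g.directed)
    out = set()
    for bits in product((0, 1), repeat=len(und)):
        edges = list(fixed)
        edges += [(a, b) if bit else (b, a) for (a, b), bit in zip(und, bits)]
        try:
            d = DAG(nodes=g.nodes, edges=edges)
        except GraphError:  # cyclic orientation
            continue
        if uncovered_colliders(d) == base_colliders:
            out.add(d)
    return frozenset(out)


def mec_members(d: DAG, *, limit: int = DEFAULT_UNDIRECTED_LIMIT) -> EquivalenceClass:
    """The complete Markov equivalence class (pattern) containing ``d``.

    Enumerates every orientation of d's skeleton and keeps the Markov
    equivalent ones; the summary is therefore the pattern of ``d``.
    """
    sk = sorted(skeleton(d))
    if len(sk) > limit:
        raise LimitError(f"{len(sk)} edges exceeds the enumeration limit {limit}")
    key = equivalence_key(d)
    members = []
    for bits in product((0, 1), repeat=len(sk)):
        edges = [(a, b) if bit else (b, a) for (a, b), bit in zip(sk, bits)]
        try:
            cand = DAG(nodes=d.nodes, edges=edges)
        except GraphError:
            continue
        if equivalence_key(cand) == key:
            members.append(cand)
    return make_class(members)


def pattern_of(d: DAG, *, limit: int = DEFAULT_UNDIRECTED_LIMIT) -> PDGraph:
    """The pattern (complete-class summary graph) of DAG ``d``.

    An edge is directed iff identically oriented in every Markov-equivalent
    same-skeleton DAG, undirected otherwise.
    """
    return mec_members(d, limit=limit).summary


@dataclass(frozen=True)
class EssentialGraphDiagnostic:
    """Outcome of validating a partially directed graph as an essential graph."""

    n_extensions: int
    valid: bool  # at least one consistent extension exists
    is_pattern_summary: bool  # input equals the summary of its own extensions


def validate_essential_graph(
    g: PDGraph, *, limit: int = DEFAULT_UNDIRECTED_LIMIT
) -> EssentialGraphDiagnostic:
    """Accept g iff it has consistent extensions; report maximality.

    ``is_pattern_summary`` is true when g equals the derived summary of its
    own extension set, i.e. g is maximally informative (every undirected
    edge of g genuinely varies across the extensions).
    """
    ext = consistent_extensions(g, limit=limit)
    if not ext:
        return EssentialGraphDiagnostic(0, False, False)
    return EssentialGraphDiagnostic(len(ext), True, make_class(ext).summary == g)
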