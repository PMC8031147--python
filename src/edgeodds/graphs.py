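"""Partially directed graphs, DAGs, and d-separation primitives.

The data model is deliberately small: a :class:`PDGraph` holds labelled nodes
plus a set of directed and a set of undirected edges (at most one edge per
unordered node pair, no self-loops, no bidirected or otherwise decorated edge
marks), and a :class:`DAG` is a fully directed, acyclic ``PDGraph``.  Graphs
compare and hash by value — by node labels and edge sets — never by object
identity, so they can live in sets and dict keys throughout the package.

The module-level functions implement the graph-theoretic vocabulary of
constraint-based causal discovery: skeletons, (uncovered) colliders, active
paths, d-separation, and the Markov-equivalence test via the classical
characterisation *same skeleton + same uncovered colliders*.  d-separation
queries are answered by collider-aware reachability (networkx); an exhaustive
simple-path implementation is provided separately as an independent oracle.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from itertools import combinations

import networkx as nx

__all__ = [
    "GraphError",
    "PDGraph",
    "DAG",
    "skeleton",
    "is_acyclic",
    "uncovered_colliders",
    "descendants",
    "is_active_path",
    "d_separated",
    "d_separated_exhaustive",
    "markov_equivalent",
    "equivalence_key",
]

_LABEL = re.compile(r"[A-Za-z0-9_]+\Z")


class GraphError(ValueError):
    """Raised for structurally invalid graphs or ill-posed graph queries."""


def _check_label(label: str) -> str:
    if not isinstance(label, str) or not _LABEL.match(label):
        raise GraphError(
            f"invalid node label {label!r}: need a non-empty string over [A-Za-z0-9_]"
        )
    return label


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered node pair in lexicographic order."""
    return (a, b) if a <= b else (b, a)


class PDGraph:
    """A partially directed graph: nodes plus directed and undirected edges.

    Parameters
    ----------
    nodes :
        Node labels (isolated nodes are legal and preserved).  Endpoints of
        edges are added automatically.
    directed :
        Ordered pairs ``(a, b)`` meaning the arrow ``a -> b``.
    undirected :
        Unordered pairs; stored with lexicographically sorted endpoints so
        that set equality is well defined.

    Raises
    ------
    GraphError
        On self-loops, invalid labels, or more than one edge between the
        same pair of nodes.
    """

    __slots__ = ("nodes", "directed", "undirected")

    nodes: frozenset[str]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[tuple[str, str]]

    def __init__(
        self,
        nodes: Iterable[str] = (),
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
    ) -> None:
        node_set = {_check_label(n) for n in nodes}
        seen_pairs: set[tuple[str, str]] = set()
        dir_set: set[tuple[str, str]] = set()
        und_set: set[tuple[str, str]] = set()
        for a, b in directed:
            _check_label(a), _check_label(b)
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            pair = _canon_pair(a, b)
            if pair in seen_pairs:
                raise GraphError(f"more than one edge between {pair[0]} and {pair[1]}")
            seen_pairs.add(pair)
            dir_set.add((a, b))
            node_set.update(pair)
        for a, b in undirected:
            _check_label(a), _check_label(b)
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            pair = _canon_pair(a, b)
            if pair in seen_pairs:
                raise GraphError(f"more than one edge between {pair[0]} and {pair[1]}")
            seen_pairs.add(pair)
            und_set.add(pair)
            node_set.update(pair)
        object.__setattr__(self, "nodes", frozenset(node_set))
        object.__setattr__(self, "directed", frozenset(dir_set))
        object.__setattr__(self, "undirected", frozenset(und_set))

    def __setattr__(self, name: str, value) -> None:  # pragma: no cover
        raise AttributeError("PDGraph instances are immutable")

    # -- value semantics ---------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PDGraph):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __hash__(self) -> int:
        return hash((self.nodes, self.directed, self.undirected))

    def __repr__(self) -> str:
        parts = [f"{a} -> {b}" for a, b in sorted(self.directed)]
        parts += [f"{a} -- {b}" for a, b in sorted(self.undirected)]
        iso = sorted(self.nodes - {n for e in self.directed | self.undirected for n in e})
        return f"{type(self).__name__}({', '.join(parts + iso) or 'empty'})"

    # -- queries -----------------------------------------------------------

    @property
    def is_fully_directed(self) -> bool:
        return not self.undirected

    def adjacent(self, a: str, b: str) -> bool:
        """True if some edge (of either kind) joins ``a`` and ``b``."""
        return _canon_pair(a, b) in skeleton(self)

    def has_node(self, n: str) -> bool:
        return n in self.nodes

    def to_digraph(self) -> "nx.DiGraph":
        """The directed part as a :class:`networkx.DiGraph` over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g


class DAG(PDGraph):
    """A fully directed acyclic graph; a member of an equivalence class."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        super().__init__(nodes=nodes, directed=edges, undirected=())
        if not nx.is_directed_acyclic_graph(self.to_digraph()):
            raise GraphError(f"directed cycle in {sorted(self.directed)}")

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self.directed

    def parents(self, x: str) -> frozenset[str]:
        self._require(x)
        return frozenset(a for a, b in self.directed if b == x)

    def children(self, x: str) -> frozenset[str]:
        self._require(x)
        return frozenset(b for a, b in self.directed if a == x)

    def _require(self, x: str) -> None:
        if x not in self.nodes:
            raise GraphError(f"unknown node {x!r}")


# ---------------------------------------------------------------------------
# graph-theoretic operators
# ---------------------------------------------------------------------------


def skeleton(g: PDGraph) -> frozenset[tuple[str, str]]:
    """Directly connected unordered node pairs, orientation and kind erased."""
    return frozenset(
        _canon_pair(a, b) for a, b in g.directed
    ) | g.undirected


def is_acyclic(g: PDGraph) -> bool:
    """True iff the (fully directed) graph has no directed cycle.

    Raises :class:`GraphError` on graphs that still contain undirected edges:
    acyclicity of a partially directed graph is not well posed until every
    edge is oriented.
    """
    if g.undirected:
        raise GraphError("graph contains undirected edges; orient them before testing acyclicity")
    return nx.is_directed_acyclic_graph(g.to_digraph())


def uncovered_colliders(g: PDGraph) -> frozenset[tuple[str, str, str]]:
    """All uncovered collider triples ``(left, mid, right)``, left < right.

    A triple qualifies when ``left -> mid <- right`` are directed edges and
    no edge of any kind joins ``left`` and ``right``.  On a partially
    directed graph only the *directed* edges contribute arrowheads, while
    adjacency (the covering test) uses the full skeleton; on a DAG this is
    the usual v-structure set.
    """
    sk = skeleton(g)
    parents: dict[str, set[str]] = {}
    for a, b in g.directed:
        parents.setdefault(b, set()).add(a)
    out = set()
    for mid, ps in parents.items():
        for left, right in combinations(sorted(ps), 2):
            if _canon_pair(left, right) not in sk:
                out.add((left, mid, right))
    return frozenset(out)


def descendants(d: DAG, x: str) -> frozenset[str]:
    """Nodes reachable from ``x`` by a directed path, excluding ``x``."""
    if x not in d.nodes:
        raise GraphError(f"unknown node {x!r}")
    return frozenset(nx.descendants(d.to_digraph(), x))


def is_active_path(d: DAG, path: Sequence[str], cond: Iterable[str] = ()) -> bool:
    """Whether ``path`` (a node sequence) is active given conditioning set ``cond``.

    A path is active when none of its noncolliders is conditioned on and
    every collider on it is conditioned on or has a conditioned descendant.
    Endpoints count as noncolliders.  Because at most one edge joins any
    node pair, a node sequence determines the path uniquely.
    """
    nodes = list(path)
    cset = frozenset(cond)
    if not nodes:
        raise GraphError("a path must contain at least one node")
    for n in nodes:
        if n not in d.nodes:
            raise GraphError(f"unknown node {n!r}")
    for u, v in zip(nodes, nodes[1:]):
        if (u, v) not in d.directed and (v, u) not in d.directed:
            raise GraphError(f"{u} and {v} are not directly connected in the DAG")
    for i, v in enumerate(nodes):
        is_collider = (
            0 < i < len(nodes) - 1
            and (nodes[i - 1], v) in d.directed
            and (nodes[i + 1], v) in d.directed
        )
        if is_collider:
            if v not in cset and not (descendants(d, v) & cset):
                return False
        elif v in cset:
            return False
    return True


def _check_sep_query(d: DAG, x: str, y: str, cond: frozenset[str]) -> None:
    for n in (x, y, *cond):
        if n not in d.nodes:
            raise GraphError(f"unknown node {n!r}")
    if x == y:
        raise GraphError("d-separation requires two distinct nodes")
    if x in cond or y in cond:
        raise GraphError("conditioning set must not contain the query nodes")


def d_separated(d: DAG, x: str, y: str, cond: Iterable[str] = ()) -> bool:
    """True iff ``x`` and ``y`` are d-separated given ``cond``.

    Answered by collider-aware reachability (networkx); see
    :func:`d_separated_exhaustive` for the path-enumeration oracle.
    """
    cset = frozenset(cond)
    _check_sep_query(d, x, y, cset)
    return nx.is_d_separator(d.to_digraph(), {x}, {y}, set(cset))


def d_separated_exhaustive(d: DAG, x: str, y: str, cond: Iterable[str] = ()) -> bool:
    """d-separation by brute force over all simple paths between x and y.

    Independent of :func:`d_separated`; intended as a correctness oracle on
    small graphs (the number of simple paths grows super-exponentially).
    """
    cset = frozenset(cond)
    _check_sep_query(d, x, y, cset)
    ug = nx.Graph()
    ug.add_nodes_from(d.nodes)
    ug.add_edges_from(d.directed)
    for p in nx.all_simple_paths(ug, x, y):
        if is_active_path(d, p, cset):
            return False
    return True


def markov_equivalent(d1: DAG, d2: DAG) -> bool:
    """Same-skeleton, same-uncovered-collider test for Markov equivalence.

    Two DAGs entail exactly the same d-separation statements iff they share
    a skeleton and a set of uncovered colliders (v-structures).
    """
    if d1.nodes != d2.nodes:
        raise GraphError("Markov equivalence is only defined over a common node set")
    return equivalence_key(d1) == equivalence_key(d2)


def equivalence_key(d: DAG) -> tuple[frozenset, frozenset]:
    """Hashable invariant characterising a DAG's Markov equivalence class."""
    return (skeleton(d), uncovered_colliders(d))
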