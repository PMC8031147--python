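"""File formats, worked fixtures, and deterministic random graphs.

Graphs travel as a plain-text edge-list dialect, one edge per line::

    # comment
    node E          # declares an isolated node
    A -> B          # directed edge
    A -- H          # undirected edge

Writing is deterministic (isolated nodes first, then edge lines sorted
lexicographically), so ``parse_graph(write_graph(g)) == g``.  DOT export is
provided for interchange with graph viewers; belief and bet tables travel
as CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .betting import CEOB, EOB
from .credence import EdgeBelief
from .graphs import DAG, GraphError, PDGraph
from .mec import EquivalenceClass, consistent_extensions, make_class
from .census import enumerate_dags

__all__ = [
    "ParseError",
    "RunConfig",
    "parse_graph",
    "parse_dag",
    "write_graph",
    "export_dot",
    "read_beliefs",
    "write_beliefs",
    "read_bets",
    "write_bets",
    "fixture",
    "FIXTURE_NAMES",
    "random_dag",
]


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class RunConfig:
    """Numeric knobs shared by the CLI and the randomized fixtures.

    tolerance : coherence-LP feasibility tolerance (probability units)
    margin : minimum certified guaranteed loss of a constructed book ($)
    stake_bound : largest |stake| the book construction may use ($)
    undirected_edge_limit : cap on 2^u member enumerations
    node_limit : cap on n! relabeling searches and n-node enumerations
    seed : base seed for every randomized fixture stream
    """

    tolerance: float = 1e-8
    margin: float = 1e-3
    stake_bound: float = 100.0
    undirected_edge_limit: int = 20
    node_limit: int = 7
    seed: int = 0

    def __post_init__(self):
        if min(self.tolerance, self.margin, self.stake_bound) <= 0:
            raise ValueError("tolerance, margin and stake_bound must be positive")
        if min(self.undirected_edge_limit, self.node_limit) <= 0:
            raise ValueError("enumeration limits must be positive")


_NODE_LINE = re.compile(r"node\s+([A-Za-z0-9_]+)\Z")
_EDGE_LINE = re.compile(r"([A-Za-z0-9_]+)\s*(->|--)\s*([A-Za-z0-9_]+)\Z")


def parse_graph(text: str) -> PDGraph:
    """Parse the edge-list dialect into a :class:`PDGraph`.

    Raises :class:`ParseError` (with a line number) on malformed lines,
    self-loops, and duplicate declarations of the same node pair.
    """
    nodes: list[str] = []
    directed: list[tuple[str, str]] = []
    undirected: list[tuple[str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if m := _NODE_LINE.match(line):
            nodes.append(m.group(1))
            continue
        m = _EDGE_LINE.match(line)
        if not m:
            raise ParseError(f"cannot parse {line!r}", lineno)
        a, op, b = m.groups()
        if a == b:
            raise ParseError(f"self-loop on {a}", lineno)
        pair = (a, b) if a < b else (b, a)
        if pair in seen_pairs:
            raise ParseError(f"duplicate edge between {pair[0]} and {pair[1]}", lineno)
        seen_pairs.add(pair)
        (directed if op == "->" else undirected).append((a, b))
    try:
        return PDGraph(nodes=nodes, directed=directed, undirected=undirected)
    except GraphError as exc:  # pragma: no cover - guarded above
        raise ParseError(str(exc)) from exc


def parse_dag(text: str) -> DAG:
    """Parse the dialect, requiring a fully directed acyclic graph."""
    g = parse_graph(text)
    if g.undirected:
        raise ParseError("expected a fully directed graph but found '--' edges")
    return DAG(nodes=g.nodes, edges=g.directed)


def write_graph(g: PDGraph) -> str:
    """Serialize to the dialect in canonical (sorted) order."""
    touched = {n for e in g.directed | g.undirected for n in e}
    lines = [f"node {n}" for n in sorted(g.nodes - touched)]
    lines += sorted(
        [f"{a} -> {b}" for a, b in g.directed] + [f"{a} -- {b}" for a, b in g.undirected]
    )
    return "\n".join(lines) + ("\n" if lines else "")


def export_dot(g: PDGraph) -> str:
    """Standard DOT; undirected edges carry ``dir=none`` to suppress arrowheads."""
    body = [f'  "{n}";' for n in sorted(g.nodes)]
    body += [f'  "{a}" -> "{b}";' for a, b in sorted(g.directed)]
    body += [f'  "{a}" -> "{b}" [dir=none];' for a, b in sorted(g.undirected)]
    return "digraph {\n" + "\n".join(body) + "\n}\n"


# ---------------------------------------------------------------------------
# tabular interfaces
# ---------------------------------------------------------------------------


def read_beliefs(source, class_ref: EquivalenceClass) -> EdgeBelief:
    """Read a beliefs CSV (columns from,to,prob) into an :class:`EdgeBelief`.

    Either ordering of an edge may be given; a missing complement is filled
    with 1 − prob.
    """
    df = pd.read_csv(source)
    required = {"from", "to", "prob"}
    if not required.issubset(df.columns):
        raise ParseError(f"beliefs CSV needs columns {sorted(required)}, got {list(df.columns)}")
    table = {(str(r["from"]), str(r["to"])): float(r["prob"]) for _, r in df.iterrows()}
    return EdgeBelief.from_pairs(class_ref, table)


def write_beliefs(beliefs: EdgeBelief, target) -> None:
    rows = [{"from": a, "to": b, "prob": p} for (a, b), p in beliefs.items()]
    pd.DataFrame(rows, columns=["from", "to", "prob"]).to_csv(target, index=False)


def read_bets(source, class_ref: EquivalenceClass) -> CEOB:
    """Read a bets CSV (columns from,to,win,lose), one EOB per row."""
    df = pd.read_csv(source)
    required = {"from", "to", "win", "lose"}
    if not required.issubset(df.columns):
        raise ParseError(f"bets CSV needs columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        raise ParseError("bets CSV contains no bets")
    bets = tuple(
        EOB(class_ref, str(r["from"]), str(r["to"]), float(r["win"]), float(r["lose"]))
        for _, r in df.iterrows()
    )
    return CEOB(bets)


def write_bets(ceob: CEOB, target) -> None:
    rows = [{"from": c.a, "to": c.b, "win": c.win, "lose": c.lose} for c in ceob.bets]
    pd.DataFrame(rows, columns=["from", "to", "win", "lose"]).to_csv(target, index=False)


# ---------------------------------------------------------------------------
# worked fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "hub_graph",
    "hub_members",
    "steve_package",
    "chain4",
    "triangle4",
    "two_node",
)


def fixture(name: str) -> Union[PDGraph, EquivalenceClass, CEOB]:
    """The package's worked objects.

    hub_graph : the essential graph with H an undirected hub of A, B, C
    hub_members : its equivalence class — the 4 DAGs in which H has at
        most one parent (two parents would create a v-structure)
    steve_package : three $6-win/$4-lose bets on A->H, B->H, C->H — the
        classic package that looks worth $3 to an everything-is-50/50
        bettor yet loses at least $2 on every member
    chain4 : the undirected 4-node chain A--B--C--D
    triangle4 : the undirected triangle A,B,C plus isolated node D
    two_node : the single undirected edge A--B
    """
    if name == "hub_graph":
        return parse_graph("A -- H\nB -- H\nC -- H\n")
    if name == "hub_members":
        return make_class(consistent_extensions(fixture("hub_graph")))
    if name == "steve_package":
        cls = fixture("hub_members")
        return CEOB(tuple(EOB(cls, x, "H", win=6.0, lose=-4.0) for x in "ABC"))
    if name == "chain4":
        return parse_graph("A -- B\nB -- C\nC -- D\n")
    if name == "triangle4":
        return parse_graph("A -- B\nA -- C\nB -- C\nnode D\n")
    if name == "two_node":
        return parse_graph("A -- B\n")
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def random_dag(n: int, m: int, seed: int, node_limit: int = 7) -> DAG:
    """A uniformly random labelled DAG with n nodes and m edges.

    Drawn by enumerating the full DAG set (n small) and indexing it with a
    seeded generator, so the same seed always returns the same DAG.
    """
    dags = enumerate_dags(n, m, node_limit=node_limit)
    if not dags:
        raise GraphError(f"no DAGs with {n} nodes and {m} edges exist")
    dags.sort(key=lambda d: sorted(d.directed))
    rng = np.random.default_rng(seed)
    return dags[int(rng.integers(len(dags)))]
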