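"""The edge-orientation-bet calculus and Dutch-book machinery.

An edge-orientation bet (EOB) on an undirected edge of an essential graph
pays ``win`` dollars if the revealed member DAG orients the edge one way and
``lose`` dollars (either sign) if it orients it the other way.  A collection
of such bets (CEOB) on one class is settled by a single revealed member.

Two expected values matter.  The *naive* expected value prices each bet from
per-edge orientation beliefs, independently of the rest of the graph.  The
*class* expected value prices the whole package from a distribution over
member DAGs.  When the beliefs are the marginals of the distribution the two
coincide (a finite-sum exchange), which is exactly why an agent accepting
only packages with nonnegative class expected value can never be caught by a
Dutch book — a package with a negative total payoff on every member.

Against *incoherent* beliefs a Dutch book can be constructed by linear
programming: choose one stake pair per undirected edge so that every
member's total payoff is below a strict negative margin while the naive
expected value stays nonnegative.  Geometrically this is the separating
hyperplane between the belief vector and the convex hull of member
orientation-indicator vectors; the construction succeeds precisely when the
beliefs lie outside the hull.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import linprog

from .credence import (
    DEFAULT_TOLERANCE,
    DagDistribution,
    EdgeBelief,
    coherence_check,
    orientation_indicator,
)
from .graphs import DAG, GraphError
from .mec import EquivalenceClass

__all__ = [
    "EOB",
    "CEOB",
    "DutchBookCheck",
    "DutchBookReport",
    "payoff",
    "naive_expected_value",
    "class_expected_value",
    "is_dutch_book",
    "theorem2_accept",
    "find_dutch_book",
    "DEFAULT_MARGIN",
    "DEFAULT_STAKE_BOUND",
]

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 1e-3
DEFAULT_STAKE_BOUND = 100.0


@dataclass(frozen=True)
class EOB:
    """An edge orientation bet: ``win`` if a -> b is revealed, else ``lose``.

    The pair (a, b) must be an undirected edge of the class summary — bets
    on compelled (directed) edges are not part of the calculus.
    """

    class_ref: EquivalenceClass
    a: str
    b: str
    win: float
    lose: float

    def __post_init__(self):
        pair = (self.a, self.b) if self.a <= self.b else (self.b, self.a)
        if pair not in self.class_ref.summary.undirected:
            raise GraphError(
                f"({self.a}, {self.b}) is not an undirected edge of the class summary"
            )
        for v in (self.win, self.lose):
            if not math.isfinite(v):
                raise ValueError("stakes must be finite")


@dataclass(frozen=True)
class CEOB:
    """A nonempty collection of EOBs on one equivalence class.

    Multiple bets on the same edge are allowed; they settle independently
    off the same revealed DAG.
    """

    bets: tuple[EOB, ...]

    def __post_init__(self):
        if not self.bets:
            raise ValueError("a CEOB must contain at least one bet")
        ref = self.bets[0].class_ref
        if any(b.class_ref != ref for b in self.bets[1:]):
            raise GraphError("all bets in a CEOB must refer to the same class")

    @property
    def class_ref(self) -> EquivalenceClass:
        return self.bets[0].class_ref

    def __len__(self) -> int:
        return len(self.bets)

    def __iter__(self):
        return iter(self.bets)


class DutchBookCheck(NamedTuple):
    """Whether a package is a guaranteed loss, and its best-case total."""

    is_book: bool
    best_case_payoff: float


@dataclass(frozen=True)
class DutchBookReport:
    """Result of a Dutch-book search against a belief table.

    When ``found``, the package ``ceob`` has total payoff below zero on
    every member — ``worst_payoff`` is the best case over members, still
    negative — yet nonnegative naive expected value ``naive_ev`` under the
    target beliefs.  Both facts are re-verified outside the LP that
    produced the package.
    """

    found: bool
    ceob: Optional[CEOB] = None
    worst_payoff: Optional[float] = None
    naive_ev: Optional[float] = None


def payoff(c: EOB, d: DAG) -> float:
    """The bettor's change in dollars when member ``d`` is revealed."""
    if d not in c.class_ref.members:
        raise GraphError("the revealed DAG is not a member of the bet's class")
    return c.win if orientation_indicator(c.a, c.b, d) else c.lose


def total_payoff(e: CEOB, d: DAG) -> float:
    """Sum of all bet payoffs when ``d`` is revealed."""
    return math.fsum(payoff(c, d) for c in e.bets)


def naive_expected_value(e: CEOB, beliefs: EdgeBelief) -> float:
    """Package value priced bet-by-bet from per-edge orientation beliefs."""
    if beliefs.class_ref != e.class_ref:
        raise GraphError("beliefs refer to a different equivalence class")
    out = []
    for c in e.bets:
        if (c.a, c.b) not in beliefs:
            raise GraphError(f"no belief for the ordered pair ({c.a}, {c.b})")
        out.append(beliefs[(c.a, c.b)] * c.win + beliefs[(c.b, c.a)] * c.lose)
    return math.fsum(out)


def class_expected_value(e: CEOB, p: DagDistribution) -> float:
    """Package value priced from a distribution over member DAGs."""
    if p.class_ref != e.class_ref:
        raise GraphError("distribution refers to a different equivalence class")
    return math.fsum(
        prob * payoff(c, d) for c in e.bets for d, prob in p.items()
    )


def is_dutch_book(e: CEOB) -> DutchBookCheck:
    """A CEOB is a Dutch book iff its total payoff is negative on every member."""
    best = max(total_payoff(e, d) for d in e.class_ref.members_sorted())
    return DutchBookCheck(best < 0, best)


def theorem2_accept(e: CEOB, p: DagDistribution) -> bool:
    """Accept a package iff its class expected value is nonnegative.

    An agent following this rule with a strictly positive distribution can
    never accept a Dutch book.  With zero-probability members the rule still
    computes, but the immunity guarantee is not stated for that case and a
    warning is attached.
    """
    if not p.strictly_positive:
        warnings.warn(
            "distribution has zero-probability members; the no-Dutch-book "
            "guarantee of the accept rule is stated for strictly positive "
            "distributions",
            stacklevel=2,
        )
    return class_expected_value(e, p) >= 0


def find_dutch_book(
    c: EquivalenceClass,
    beliefs: EdgeBelief,
    margin: float = DEFAULT_MARGIN,
    stake_bound: float = DEFAULT_STAKE_BOUND,
    tol: float = DEFAULT_TOLERANCE,
) -> DutchBookReport:
    """Construct a Dutch book against incoherent edge beliefs, if one exists.

    Solves an LP over one (win, lose) stake pair per undirected summary
    edge, maximising the uniform margin s by which every member's total
    payoff is forced to at most −s, subject to nonnegative naive expected
    value under ``beliefs`` and ``|stake| <= stake_bound``.  Succeeds when
    the optimal margin reaches ``margin``.  Coherent beliefs (per
    :func:`coherence_check` at ``tol``) admit no book and return
    ``found=False`` immediately.

    One bet per edge suffices: two bets on one edge collapse to their stake
    sums, so the restriction loses no generality in construction (evaluation
    of multi-bet packages remains unrestricted).
    """
    if margin <= 0 or stake_bound <= 0:
        raise ValueError("margin and stake_bound must be positive")
    if beliefs.class_ref != c:
        raise GraphError("beliefs refer to a different equivalence class")
    coh = coherence_check(c, beliefs, tol=tol)
    if coh.feasible:
        logger.info("beliefs are coherent (max violation %.3g); no Dutch book exists",
                    coh.max_violation)
        return DutchBookReport(found=False)

    edges = list(c.undirected_edges)
    members = c.members_sorted()
    n_e = len(edges)
    # variables: win_0, lose_0, ..., win_{u-1}, lose_{u-1}, s  ; maximise s
    cost = np.zeros(2 * n_e + 1)
    cost[-1] = -1.0
    rows, rhs = [], []
    for d in members:  # total payoff + s <= 0
        row = np.zeros(2 * n_e + 1)
        for j, (a, b) in enumerate(edges):
            ind = orientation_indicator(a, b, d)
            row[2 * j] = ind
            row[2 * j + 1] = 1 - ind
        row[-1] = 1.0
        rows.append(row)
        rhs.append(0.0)
    ev_row = np.zeros(2 * n_e + 1)  # -naive EV <= 0
    for j, (a, b) in enumerate(edges):
        ev_row[2 * j] = -beliefs[(a, b)]
        ev_row[2 * j + 1] = -beliefs[(b, a)]
    rows.append(ev_row)
    rhs.append(0.0)
    res = linprog(
        cost,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(-stake_bound, stake_bound)] * (2 * n_e) + [(0, None)],
        method="highs",
    )
    logger.debug("dutch-book LP status=%s margin=%s", res.status, -res.fun if res.success else None)
    if res.status != 0 or res.x[-1] < margin:
        logger.info("no Dutch book certified at margin %.3g / stake bound %.3g", margin, stake_bound)
        return DutchBookReport(found=False)

    stakes = list(res.x[: 2 * n_e])
    bets = [
        EOB(c, a, b, win=stakes[2 * j], lose=stakes[2 * j + 1])
        for j, (a, b) in enumerate(edges)
    ]
    ceob = CEOB(tuple(bets))
    ev = naive_expected_value(ceob, beliefs)
    for _ in range(8):
        if ev >= 0:
            break
        # LP feasibility slack can leave the EV a hair below zero; shifting
        # one bet's win and lose equally raises the EV by the shift (the two
        # beliefs sum to one) and costs that much guaranteed margin — the
        # extra 1e-9 headroom absorbs float residue, negligible vs `margin`.
        shift = -ev + 1e-9
        first = bets[0]
        bets[0] = EOB(c, first.a, first.b, first.win + shift, first.lose + shift)
        ceob = CEOB(tuple(bets))
        ev = naive_expected_value(ceob, beliefs)
    check = is_dutch_book(ceob)
    if not check.is_book or ev < 0:  # pragma: no cover - defensive re-verification
        logger.warning("LP produced an unverifiable book (best case %.3g, EV %.3g)",
                       check.best_case_payoff, ev)
        return DutchBookReport(found=False)
    return DutchBookReport(
        found=True, ceob=ceob, worst_payoff=check.best_case_payoff, naive_ev=ev
    )
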