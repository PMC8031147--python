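"""Credences over class members and edge-orientation beliefs.

Two ways of holding beliefs about how an undirected edge will turn out:

* a :class:`DagDistribution` — a probability distribution over the member
  DAGs of an equivalence class, the *graph-level* credence from which edge
  orientation probabilities follow by marginalisation; and
* an :class:`EdgeBelief` — per-edge orientation probabilities assigned
  directly, which may or may not be *coherent*, i.e. reproducible as the
  marginals of some distribution over members.

Coherence is a linear feasibility question: does a point of the probability
simplex over members map onto the stated edge marginals?  It is decided by a
small linear program (HiGHS) that minimises the worst marginal violation; a
belief table is coherent when that minimum is within tolerance, in which
case the minimiser is returned as a witness distribution.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .graphs import DAG, GraphError, skeleton
from .mec import EquivalenceClass

__all__ = [
    "DagDistribution",
    "EdgeBelief",
    "CoherenceResult",
    "orientation_indicator",
    "uniform_distribution",
    "orientation_probability",
    "orientation_table",
    "coherence_check",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 1e-8
_SUM_TOL = 1e-9


def orientation_indicator(a: str, b: str, d: DAG) -> int:
    """1 iff the arrow ``a -> b`` is present in ``d``, else 0.

    Returns 0 both for the reverse orientation and when no edge joins the
    pair at all.
    """
    for n in (a, b):
        if n not in d.nodes:
            raise GraphError(f"unknown node {n!r}")
    return 1 if (a, b) in d.directed else 0


class DagDistribution:
    """A probability distribution over the member DAGs of a class.

    ``prob`` must assign a probability to exactly the members; values must
    be nonnegative and sum to one (within 1e-9).  Zero-probability members
    are legal, but the Dutch-book immunity guarantee of the accept rule is
    stated for strictly positive distributions — check
    :attr:`strictly_positive`.
    """

    def __init__(self, class_ref: EquivalenceClass, prob: Mapping[DAG, float]):
        if set(prob) != set(class_ref.members):
            raise GraphError("distribution keys must be exactly the class members")
        vals = list(prob.values())
        if any(v < -_SUM_TOL for v in vals):
            raise ValueError("probabilities must be nonnegative")
        total = math.fsum(vals)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        self.class_ref = class_ref
        self.prob = {d: max(0.0, float(p)) for d, p in prob.items()}

    @property
    def strictly_positive(self) -> bool:
        return all(p > 0.0 for p in self.prob.values())

    def __getitem__(self, d: DAG) -> float:
        return self.prob[d]

    def items(self):
        return ((d, self.prob[d]) for d in self.class_ref.members_sorted())

    def __repr__(self) -> str:
        return f"DagDistribution({[round(p, 6) for _, p in self.items()]})"


class EdgeBelief:
    """Per-ordered-pair orientation probabilities on a class's undirected edges.

    The belief table is defined on *both* orderings of every undirected edge
    of the class summary, and nothing else; complements must sum to one.
    Beliefs about pairs the summary already directs are rejected: bets, and
    therefore beliefs, concern unoriented edges only.
    """

    def __init__(self, class_ref: EquivalenceClass, belief: Mapping[tuple[str, str], float]):
        required = set()
        for a, b in class_ref.summary.undirected:
            required.add((a, b))
            required.add((b, a))
        extra = set(belief) - required
        if extra:
            raise GraphError(
                f"beliefs on pairs that are not undirected summary edges: {sorted(extra)}"
            )
        missing = required - set(belief)
        if missing:
            raise GraphError(f"beliefs missing for ordered pairs: {sorted(missing)}")
        for (a, b), p in belief.items():
            if not (-_SUM_TOL <= p <= 1 + _SUM_TOL):
                raise ValueError(f"belief for ({a},{b}) outside [0,1]: {p!r}")
        for a, b in class_ref.summary.undirected:
            s = belief[(a, b)] + belief[(b, a)]
            if abs(s - 1.0) > _SUM_TOL:
                raise ValueError(f"beliefs for {a}--{b} sum to {s!r}, not 1")
        self.class_ref = class_ref
        self.belief = {k: min(1.0, max(0.0, float(v))) for k, v in belief.items()}

    @classmethod
    def from_pairs(
        cls, class_ref: EquivalenceClass, belief: Mapping[tuple[str, str], float]
    ) -> "EdgeBelief":
        """Build a table, filling each missing complement with 1 − p."""
        full = dict(belief)
        for a, b in class_ref.summary.undirected:
            if (a, b) in full and (b, a) not in full:
                full[(b, a)] = 1.0 - full[(a, b)]
            elif (b, a) in full and (a, b) not in full:
                full[(a, b)] = 1.0 - full[(b, a)]
        return cls(class_ref, full)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.belief[pair]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.belief

    def items(self):
        return iter(sorted(self.belief.items()))

    def __len__(self) -> int:
        return len(self.belief)

    def __repr__(self) -> str:
        body = ", ".join(f"P({a}->{b})={p:.4g}" for (a, b), p in self.items())
        return f"EdgeBelief({body})"


@dataclass(frozen=True)
class CoherenceResult:
    """Outcome of a coherence (linear feasibility) check.

    ``feasible`` iff some distribution over members reproduces the beliefs
    within tolerance; ``witness`` is such a distribution when one exists;
    ``max_violation`` is the largest achievable-vs-stated marginal gap (for
    the witness when feasible, the best possible when not).
    """

    feasible: bool
    witness: Optional[DagDistribution]
    max_violation: float


def uniform_distribution(c: EquivalenceClass) -> DagDistribution:
    """The uniform distribution over the class members."""
    k = len(c.members)
    return DagDistribution(c, {d: 1.0 / k for d in c.members})


def orientation_probability(p: DagDistribution, a: str, b: str) -> float:
    """P(a -> b) under ``p``: the distribution-weighted orientation indicator."""
    sk = skeleton(p.class_ref.summary)
    pair = (a, b) if a <= b else (b, a)
    if pair not in sk:
        raise GraphError(f"{a} and {b} are not adjacent in the class skeleton")
    return math.fsum(
        prob * orientation_indicator(a, b, d) for d, prob in p.prob.items()
    )


def orientation_table(p: DagDistribution) -> EdgeBelief:
    """Induced beliefs on both orderings of every undirected summary edge."""
    table = {}
    for a, b in p.class_ref.summary.undirected:
        q = orientation_probability(p, a, b)
        table[(a, b)] = q
        table[(b, a)] = 1.0 - q
    return EdgeBelief(p.class_ref, table)


def coherence_check(
    c: EquivalenceClass, beliefs: EdgeBelief, tol: float = DEFAULT_TOLERANCE
) -> CoherenceResult:
    """Decide whether ``beliefs`` are the marginals of some member distribution.

    Solves ``min_t { t : x >= 0, sum x = 1, |I x - p| <= t }`` where ``I``
    stacks orientation indicators of the believed pairs over the members.
    Feasible iff the optimum is within ``tol``; the minimiser is returned as
    the witness.  Equalities are deliberately relaxed to ±tol: floating-point
    beliefs from users will never satisfy exact rational equalities.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if beliefs.class_ref != c:
        raise GraphError("beliefs refer to a different equivalence class")
    members = c.members_sorted()
    k = len(members)
    rows = list(beliefs.items())
    if not rows:
        return CoherenceResult(True, uniform_distribution(c), 0.0)

    a_mat = np.array(
        [[orientation_indicator(a, b, d) for d in members] for (a, b), _ in rows],
        dtype=float,
    )
    b_vec = np.array([p for _, p in rows], dtype=float)
    # variables: x_1..x_k, t ; minimise t
    cost = np.zeros(k + 1)
    cost[-1] = 1.0
    ones_t = np.ones((len(rows), 1))
    a_ub = np.vstack(
        [np.hstack([a_mat, -ones_t]), np.hstack([-a_mat, -ones_t])]
    )
    b_ub = np.concatenate([b_vec, -b_vec])
    a_eq = np.zeros((1, k + 1))
    a_eq[0, :k] = 1.0
    res = linprog(
        cost,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=[1.0],
        bounds=[(0, None)] * k + [(0, None)],
        method="highs",
    )
    if res.status != 0:  # pragma: no cover - the LP is always feasible
        raise RuntimeError(f"coherence LP failed: {res.message}")
    x = np.clip(res.x[:k], 0.0, None)
    x /= x.sum()
    witness = DagDistribution(c, dict(zip(members, x)))
    achieved = float(np.max(np.abs(a_mat @ x - b_vec)))
    if achieved <= tol:
        return CoherenceResult(True, witness, achieved)
    return CoherenceResult(False, None, max(achieved, float(res.x[-1])))
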