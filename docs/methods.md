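# Methods

## Graphs and equivalence

A partially directed graph is a labelled node set with directed and
undirected edges, at most one edge per unordered pair, no self-loops, and
no other edge marks (no bidirected edges — latent confounders are out of
scope; see Limitations). A DAG is a fully directed acyclic such graph.
Two DAGs are Markov equivalent iff they share a skeleton and a set of
uncovered colliders (v-structures); the package tests equivalence through
that characterisation and separately verifies, on every 4-node DAG, that
it coincides with equality of the full d-separation profile computed by
an exhaustive simple-path oracle.

d-separation queries are answered by collider-aware reachability
(`networkx.is_d_separator`). The path-based oracle
(`d_separated_exhaustive`) enumerates simple paths and applies the
active-path rule directly: a path is active given **C** when no
noncollider on it (endpoints included) is in **C** and every collider is
in **C** or has a descendant in **C**. The definition of a path does not
require simplicity; for d-separation the two readings agree (an active
walk exists iff an active simple path does), so the restriction to simple
paths in the oracle is harmless. The two routes are cross-checked on
random 5-node DAGs over every conditioning set.

## Equivalence classes as member sets

An essential graph is represented by its explicit member set; the summary
partially directed graph is always *derived*: an edge is drawn directed
iff every member orients it identically. This choice matters for
background-knowledge-restricted classes, which may be strict subsets of a
full pattern: an edge constant across a restricted member set is rendered
directed in the summary even if the full pattern leaves it undirected.

`consistent_extensions` enumerates all 2^u orientations of the u
undirected edges and keeps those that are acyclic and preserve the
uncovered-collider set computed from the input's directed edges (covering
is judged against the full skeleton, so a collider shielded by an
undirected edge counts as covered). Brute force was chosen over
Meek-rule propagation deliberately: at the node counts this package
targets (a hard limit of u ≤ 20 undirected edges, n ≤ 7 nodes for
censuses) it is instantaneous, has no rule-completeness caveats, and
doubles as its own oracle. An input is a valid essential graph iff its
extension set is non-empty; `validate_essential_graph` additionally
reports whether the input equals the summary of its own extensions
(i.e. is maximally informative).

## Credences, coherence, and the LP

A `DagDistribution` assigns probabilities (nonnegative, summing to 1
within 1e-9) to exactly the members. The orientation probability of an
ordered pair is the distribution-weighted orientation indicator. An
`EdgeBelief` assigns a probability to both orderings of every undirected
summary edge (complements must sum to 1; beliefs about compelled edges
are rejected — the bet calculus concerns unoriented edges only).

Coherence of a belief table is linear feasibility: does a point x of the
probability simplex over the k members satisfy I·x = p, where I stacks
the orientation indicator rows of the believed pairs? The implementation
solves min t subject to x ≥ 0, Σx = 1, |I·x − p| ≤ t with HiGHS and
declares coherence when the cleaned-up minimiser reproduces the beliefs
within tolerance (default 1e-8). The equalities are relaxed to ±tol on
purpose: user-supplied floating-point beliefs never satisfy exact
rational equalities. The minimiser is returned as a witness
distribution; on failure the smallest achievable violation is reported.

## Bets and Dutch-book construction

A bet on edge (A, B) pays R if A→B is revealed, L otherwise; a package
(CEOB) is a nonempty set of bets on one class settled by one revealed
member. Two pricings are implemented: the naive expected value
Σ p(A,B)·R + p(B,A)·L from per-edge beliefs, and the class expected
value Σ_D P(D)·δ(D) from a member distribution. When the beliefs are the
marginals of the distribution the two coincide exactly (exchange of
finite sums); this identity is property-tested to 1e-9.

The accept rule — take a package iff its class expected value is ≥ 0 —
is immune to Dutch books when the distribution is strictly positive.
Zero-probability members are allowed in the data model but flagged with a
warning at accept time, since the immunity argument divides by P(D).

`find_dutch_book` searches for a certified book against a belief table:
variables are one (win, lose) stake pair per undirected summary edge plus
a slack s; maximise s subject to (total payoff on member D) ≤ −s for
every D, naive expected value ≥ 0, |stake| ≤ stake_bound (default 100),
s ≥ 0. A book is certified when the optimum reaches the margin (default
1e-3 money units) — a strict-inequality guard that raw LP feasibility
cannot express. One bet per edge loses no generality in construction,
because multiple bets on one edge collapse to their stake sums
(evaluation of multi-bet packages remains unrestricted). Every returned
package is re-verified outside the LP (guaranteed loss on every member,
nonnegative naive EV); LP feasibility slack on the EV constraint is
absorbed by shifting one bet's win and lose equally, which costs the
shift (≈1e-9) of guaranteed margin. Geometrically the construction is
the separating hyperplane between the belief vector and the convex hull
of member indicator vectors, so it succeeds exactly when
`coherence_check` fails; the package treats this duality as an
*empirical* property (tested on randomized beliefs over all 4-node /
3-edge classes), not a theorem it relies on. Near the hull boundary the
two can disagree by numerical scale: incoherence smaller than about
margin/stake_bound (≈1e-5 in probability units at the defaults) is
detected by the coherence LP but not certified as a book.

## Census conventions

`imbalance_census(n, m)` enumerates all C(n(n−1)/2, m)·2^m labelled
directed graphs, discards cyclic ones, partitions the DAGs by
(skeleton, v-structures), and groups class summaries identical up to node
relabeling; canonical forms are computed by brute-force minimisation over
all n! relabelings (exact, and cheap at n ≤ 7). Isolated nodes are kept
throughout — the triangle-plus-isolated-node type requires them.

Undirected-edge instances are counted **once per DAG**: a class with k
members and u undirected summary edges contributes k·u instances, each at
the larger of the two orientation probabilities under the uniform
distribution over the class (bucketed at 6 decimals). An instance is
imbalanced when that maximum exceeds ½. For 4 nodes and 3 edges this
yields 312 instances — 144 at 0.75 and 168 at 0.5 — hence the 46%
headline; the per-DAG convention is the one under which the type-wise
tallies (96 + 48 imbalanced vs 48 + 48 + 72 balanced) add up. Boundary
cases behave as expected: complete patterns and patterns with m ≤ 1
produce only 0.5 instances.

## Randomized fixtures and problem sizes

`random_dag(n, m, seed)` draws uniformly from the fully enumerated DAG
set (n ≤ 7), so fixture streams are bit-identical for a fixed seed.
Property tests run at the scales the theory is exercised at in the source
material: all 543 DAGs on 4 labeled nodes for the d-separation
characterisation, all 4-node/3-edge classes (60 of them) with 1,000
random packages each for accept-rule immunity, and a few randomized
belief tables per class for the construction/coherence duality. Belief
samples are drawn from [0.02, 0.98] per edge — interior points of the
cube, away from the numerical boundary regime described above.

What the synthetic inputs do not emulate: essential graphs *estimated
from data* (sampling error, ensemble/bootstrap frequencies), classes too
large to enumerate, and latent-variable structures. Passing tests show
the calculus is correct on explicit classes, not that any particular
learned graph is trustworthy.

## Limitations

* Essential graphs only: no mixed ancestral graphs, no bidirected edges,
  no m-separation, hence no unmeasured-confounder semantics.
* Enumeration is exponential by design; the limits (u ≤ 20, n ≤ 7) are
  guards, not scalability claims. Efficient large-class machinery
  (clique-tree counting, Meek propagation) is out of scope.
* The construction/coherence duality is certified per instance, not
  proved in general; disagreements beyond the numerical boundary regime
  would be a research finding and are asserted against in tests rather
  than silently tolerated.
* Money is linear: no utilities, no sequential or conditional bets, no
  bets on compelled edges or across multiple essential graphs.
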