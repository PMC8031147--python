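# edgeodds

Quantitative interpretation of undirected edges in essential graphs
(CPDAGs), for people who use causal discovery output: epidemiologists,
biostatisticians and systems biologists reading a learned Markov
equivalence class and wondering "how likely is it that this undirected
edge really points left-to-right?"

## The problem

Constraint-based causal discovery rarely returns a single DAG. It returns
an **essential graph** *G*: a partially directed graph whose directed
edges are compelled in every member of a Markov equivalence class of DAGs
and whose undirected edges vary across members. A tempting reading of an
undirected edge *A*—*B* is "50/50 either way". That reading is wrong, and
measurably so: because members must share a skeleton and a set of
v-structures (uncovered colliders *A* → *B* ← *C* with *A*, *B*
non-adjacent), edge orientations are *dependent*. In the 4-node hub graph
with undirected edges *A*—*H*, *B*—*H*, *C*—*H*, no member gives *H* two
parents, so under any distribution over the 4 members at most one of
P(*A*→*H*), P(*B*→*H*), P(*C*→*H*) can reach ½ — assigning ½ to all three
is *incoherent*, and an incoherent bettor can be **Dutch booked**: sold a
package of edge-orientation bets with apparently positive expected value
that loses money on every member.

## What the package computes

For an essential graph *G* with member DAGs *D* ∈ *G*:

* **Members.** `consistent_extensions(g)` enumerates all acyclic
  orientations of the undirected edges that neither create nor destroy an
  uncovered collider; `mec_members(d)` / `pattern_of(d)` go the other way.
* **Orientation probabilities.** Given a distribution *P_G* over members,
  P(*A*→*B*) = Σ_D *P_G*(D) · **I**(*A*→*B* ∈ D)
  (`orientation_probability`, `orientation_table`).
* **Coherence.** `coherence_check(c, beliefs)` decides by linear
  programming whether a table of per-edge beliefs P(*A*,*B*) equals the
  marginals of *some* distribution over members — i.e. whether the belief
  vector lies in the convex hull of the members' orientation-indicator
  vectors.
* **Bets.** An edge orientation bet 〈*G*, *A*, *B*, *R*, *L*〉 pays
  δ(D) = *R*·**I**(*A*→*B* ∈ D) + *L*·(1 − **I**). `naive_expected_value`
  prices a package edge-by-edge from beliefs; `class_expected_value`
  prices it from a member distribution; `is_dutch_book` checks for a
  guaranteed loss; `theorem2_accept` is the accept-iff-EV≥0 rule that is
  provably immune to Dutch books under a strictly positive member
  distribution; `find_dutch_book` constructs a certified book against any
  incoherent belief table (a separating-hyperplane LP).
* **Census.** `imbalance_census(n, m)` enumerates every n-node, m-edge
  DAG, partitions them into equivalence classes, groups the patterns into
  node-permutation types and tallies how many undirected-edge instances
  are *imbalanced* (larger orientation probability > ½ under the uniform
  distribution over the class).

## Worked example

The hub graph, from a file `hub.txt` containing three lines
`A -- H`, `B -- H`, `C -- H`:

```sh
$ edgeodds orient-probs hub.txt
P(A -> H) = 0.25
P(B -> H) = 0.25
P(C -> H) = 0.25
P(H -> A) = 0.75
P(H -> B) = 0.75
P(H -> C) = 0.75
```

Under the uniform distribution over the 4 members, each spoke points *into*
the hub with probability ¼, not ½ — only one member orients any given
spoke inward. Against someone who nevertheless believes all three edges
are 50/50 (`naive.csv` with rows `A,H,0.5` etc.):

```sh
$ edgeodds dutchbook hub.txt naive.csv
Dutch book found:
  on A -> H: win +100, lose -100
  on B -> H: win +100, lose -100
  on C -> H: win +100, lose -100
best-case total payoff: -100
naive expected value under the stated beliefs: +0
```

Three even-money $100 bets look worth $0 to the 50/50 bettor, but at most
one can win, so every member costs them at least $100. The same structure
drives the classic hand-built package (`fixture("steve_package")`): win $6
/ lose $4 on each spoke looks worth +$3 at 50/50 beliefs yet pays at best
$6 − $4 − $4 = −$2.

How common are such imbalanced edges? Exhaustively, for 4 nodes and 3
edges:

```sh
$ edgeodds census --nodes 4 --edges 3
160 directed graphs over 20 skeletons
8 cyclic, 152 DAGs
6 node-permutation pattern types:
    48 DAGs of type PDGraph(A -- B, A -- C, B -- D)
    48 DAGs of type PDGraph(A -> B, C -> B, A -- D)
    24 DAGs of type PDGraph(A -- B, A -- C, B -- C, D)
    16 DAGs of type PDGraph(A -- B, A -- C, A -- D)
    12 DAGs of type PDGraph(A -> B, B -> C, D -> B)
     4 DAGs of type PDGraph(A -> B, C -> B, D -> B)
  168 undirected-edge instances at max orientation probability 0.5
  144 undirected-edge instances at max orientation probability 0.75
imbalanced fraction: 0.4615 (~46%)
```

Counting one instance per undirected pattern edge per DAG, 144 of 312
instances (≈46%) are 75/25 edges — undirected chains and hubs, not just
exotic graphs, carry them.

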