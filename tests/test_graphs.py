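"""Graph data model, colliders, active paths, and d-separation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgeodds import (
    DAG,
    GraphError,
    PDGraph,
    d_separated,
    d_separated_exhaustive,
    descendants,
    is_active_path,
    is_acyclic,
    markov_equivalent,
    random_dag,
    skeleton,
    uncovered_colliders,
)
from edgeodds.graphs import equivalence_key

CHAIN = DAG(edges=[("A", "B"), ("B", "C")])
COLLIDER = DAG(nodes="ABC", edges=[("A", "B"), ("C", "B")])
HUB_OUT = DAG(edges=[("H", "A"), ("H", "B"), ("H", "C")])


class TestConstruction:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphError, match="self-loop"):
            PDGraph(directed=[("A", "A")])

    def test_rejects_parallel_edges(self):
        with pytest.raises(GraphError, match="more than one edge"):
            PDGraph(directed=[("A", "B")], undirected=[("B", "A")])

    def test_rejects_bad_labels(self):
        with pytest.raises(GraphError, match="invalid node label"):
            PDGraph(nodes=["a b"])

    def test_undirected_edges_canonicalized(self):
        assert PDGraph(undirected=[("B", "A")]) == PDGraph(undirected=[("A", "B")])

    def test_value_equality_across_classes(self):
        # a DAG equals a fully directed PDGraph with the same edges
        assert DAG(edges=[("A", "B")]) == PDGraph(directed=[("A", "B")])

    def test_dag_rejects_cycle(self):
        with pytest.raises(GraphError, match="cycle"):
            DAG(edges=[("A", "B"), ("B", "C"), ("C", "A")])

    def test_graphs_are_immutable(self):
        g = PDGraph(nodes="AB")
        with pytest.raises(AttributeError):
            g.nodes = frozenset()

    def test_empty_graph_is_legal_and_acyclic(self):
        g = DAG()
        assert not g.nodes and is_acyclic(g)


class TestSkeleton:
    def test_hub_graph(self, hub_graph):
        assert skeleton(hub_graph) == {("A", "H"), ("B", "H"), ("C", "H")}

    def test_edgeless_graph(self):
        assert skeleton(PDGraph(nodes="AB")) == frozenset()

    def test_orientation_erased(self):
        chain_pd = PDGraph(undirected=[("A", "B"), ("B", "C")])
        assert skeleton(COLLIDER) == skeleton(chain_pd) == {("A", "B"), ("B", "C")}

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(0, 6))
    def test_invariant_under_reorientation(self, seed, m):
        d = random_dag(4, m, seed)
        flipped = PDGraph(
            nodes=d.nodes,
            directed=[(b, a) for a, b in sorted(d.directed)[: m // 2]]
            + sorted(d.directed)[m // 2:],
        )
        assert skeleton(flipped) == skeleton(d)


class TestAcyclicity:
    def test_three_cycle(self):
        g = PDGraph(directed=[("A", "B"), ("B", "C"), ("C", "A")])
        assert not is_acyclic(g)

    def test_hub_member(self):
        assert is_acyclic(PDGraph(directed=[("H", "A"), ("H", "B"), ("H", "C")]))

    def test_rejects_undirected_edges(self):
        with pytest.raises(GraphError, match="undirected"):
            is_acyclic(PDGraph(undirected=[("A", "B")]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_source_removal_oracle(self, seed):
        # Kahn-style peeling: a directed graph is acyclic iff repeatedly
        # deleting in-degree-zero nodes consumes the whole graph.
        d = random_dag(5, 6, seed)
        edges = set(d.directed)
        nodes = set(d.nodes)
        while True:
            sources = {n for n in nodes if not any(b == n for _, b in edges)}
            if not sources:
                break
            nodes -= sources
            edges = {(a, b) for a, b in edges if a not in sources}
        assert is_acyclic(PDGraph(nodes=d.nodes, directed=d.directed)) == (not nodes)


class TestColliders:
    def test_simple_v_structure(self):
        assert uncovered_colliders(COLLIDER) == {("A", "B", "C")}

    def test_hub_members_have_none(self, hub_class):
        for d in hub_class:
            assert uncovered_colliders(d) == frozenset()

    def test_covered_collider_excluded(self):
        d = DAG(edges=[("A", "B"), ("C", "B"), ("A", "C")])
        assert uncovered_colliders(d) == frozenset()


class TestDescendants:
    def test_chain(self):
        assert descendants(CHAIN, "A") == {"B", "C"}

    def test_sink_is_empty(self):
        assert descendants(CHAIN, "C") == frozenset()

    def test_hub_source(self):
        assert descendants(HUB_OUT, "H") == {"A", "B", "C"}

    def test_unknown_node(self):
        with pytest.raises(GraphError, match="unknown node"):
            descendants(CHAIN, "Z")


class TestActivePath:
    @pytest.mark.parametrize(
        "dag, path, cond, active",
        [
            (CHAIN, "ABC", set(), True),
            (CHAIN, "ABC", {"B"}, False),  # conditioned noncollider blocks
            (COLLIDER, "ABC", set(), False),  # unconditioned collider blocks
            (COLLIDER, "ABC", {"B"}, True),  # conditioning opens the collider
        ],
    )
    def test_rules(self, dag, path, cond, active):
        assert is_active_path(dag, list(path), cond) is active

    def test_descendant_of_collider_opens(self):
        d = DAG(edges=[("A", "B"), ("C", "B"), ("B", "D")])
        assert is_active_path(d, "ABC", {"D"})

    def test_non_path_rejected(self):
        with pytest.raises(GraphError, match="not directly connected"):
            is_active_path(CHAIN, ["A", "C"], set())


class TestDSeparation:
    @pytest.mark.parametrize(
        "dag, x, y, cond, sep",
        [
            (CHAIN, "A", "C", {"B"}, True),
            (CHAIN, "A", "C", set(), False),
            (COLLIDER, "A", "C", set(), True),
            (COLLIDER, "A", "C", {"B"}, False),
        ],
    )
    def test_chain_and_collider(self, dag, x, y, cond, sep):
        assert d_separated(dag, x, y, cond) is sep
        assert d_separated_exhaustive(dag, x, y, cond) is sep

    def test_query_node_in_conditioning_set_rejected(self):
        with pytest.raises(GraphError):
            d_separated(CHAIN, "A", "C", {"A"})

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), m=st.integers(0, 8))
    def test_reachability_matches_path_enumeration(self, seed, m):
        """Collider-aware reachability agrees with the exhaustive simple-path
        oracle on 5-node DAGs, over every query and conditioning set."""
        from itertools import combinations

        d = random_dag(5, m, seed)
        nodes = sorted(d.nodes)
        for x, y in combinations(nodes, 2):
            rest = [n for n in nodes if n not in (x, y)]
            for r in range(len(rest) + 1):
                for cond in combinations(rest, r):
                    assert d_separated(d, x, y, cond) == d_separated_exhaustive(
                        d, x, y, cond
                    )


class TestMarkovEquivalence:
    def test_hub_members_pairwise_equivalent(self, hub_class):
        members = hub_class.members_sorted()
        for d1 in members:
            for d2 in members:
                assert markov_equivalent(d1, d2)

    def test_collider_vs_chain(self):
        chain = DAG(edges=[("A", "B"), ("B", "C")])
        assert not markov_equivalent(chain, COLLIDER)

    def test_node_set_mismatch(self):
        with pytest.raises(GraphError, match="node set"):
            markov_equivalent(CHAIN, DAG(nodes="ABCD", edges=[("A", "B"), ("B", "C")]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seeds=st.tuples(*[st.integers(0, 10_000)] * 3), m=st.integers(0, 6))
    def test_is_an_equivalence_relation(self, seeds, m):
        ds = [random_dag(4, m, s) for s in seeds]
        for d in ds:
            assert markov_equivalent(d, d)  # reflexive
        for d1 in ds:
            for d2 in ds:
                assert markov_equivalent(d1, d2) == markov_equivalent(d2, d1)
        d1, d2, d3 = ds
        if markov_equivalent(d1, d2) and markov_equivalent(d2, d3):
            assert markov_equivalent(d1, d3)

    def test_characterisation_matches_dsep_profiles_three_nodes(self):
        """On all 3-node DAGs, identical d-separation profiles coincide
        exactly with identical (skeleton, uncovered colliders)."""
        from itertools import combinations

        from edgeodds import enumerate_dags

        dags = [d for m in range(4) for d in enumerate_dags(3, m)]

        def profile(d):
            out = []
            nodes = sorted(d.nodes)
            for x, y in combinations(nodes, 2):
                rest = [n for n in nodes if n not in (x, y)]
                for r in range(len(rest) + 1):
                    for cond in combinations(rest, r):
                        out.append(d_separated_exhaustive(d, x, y, cond))
            return tuple(out)

        profiles = {d: profile(d) for d in dags}
        for d1 in dags:
            for d2 in dags:
                assert (profiles[d1] == profiles[d2]) == (
                    equivalence_key(d1) == equivalence_key(d2)
                )
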