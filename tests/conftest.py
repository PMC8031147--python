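import pytest

from edgeodds import fixture, imbalance_census, partition_by_equivalence, enumerate_dags


@pytest.fixture(scope="session")
def hub_graph():
    return fixture("hub_graph")


@pytest.fixture(scope="session")
def hub_class():
    return fixture("hub_members")


@pytest.fixture(scope="session")
def steve_package():
    return fixture("steve_package")


@pytest.fixture(scope="session")
def two_node_class():
    from edgeodds import consistent_extensions, make_class

    return make_class(consistent_extensions(fixture("two_node")))


@pytest.fixture(scope="session")
def census43():
    """The full 4-node/3-edge census (computed once per session)."""
    return imbalance_census(4, 3)


@pytest.fixture(scope="session")
def classes43():
    """All Markov equivalence classes of 4-node/3-edge DAGs."""
    return partition_by_equivalence(enumerate_dags(4, 3))
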