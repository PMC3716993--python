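import pytest

from cophen.tree_model import parse_newick
from cophen.treespaces import enumerate_space
from cophen.experiments import exhaustive_correlations

#: 7-taxon worked example with nested taxon 7 (internal node labeled 7
#: with single child 1); all arc weights 1.
TABLE1_NEWICK = "((5,6),((2,(1)7),(3,4)));"

#: its 28 cophenetic values, keyed by taxon pair (diagonal = depths)
TABLE1_VALUES = {
    (1, 1): 4, (1, 2): 2, (1, 3): 1, (1, 4): 1, (1, 5): 0, (1, 6): 0, (1, 7): 3,
    (2, 2): 3, (2, 3): 1, (2, 4): 1, (2, 5): 0, (2, 6): 0, (2, 7): 2,
    (3, 3): 3, (3, 4): 2, (3, 5): 0, (3, 6): 0, (3, 7): 1,
    (4, 4): 3, (4, 5): 0, (4, 6): 0, (4, 7): 1,
    (5, 5): 2, (5, 6): 1, (5, 7): 0,
    (6, 6): 2, (6, 7): 0,
    (7, 7): 3,
}


@pytest.fixture(scope="session")
def table1_tree():
    return parse_newick(TABLE1_NEWICK)


@pytest.fixture(scope="session")
def ut3_trees():
    return list(enumerate_space("UT", 3))


@pytest.fixture(scope="session")
def t4_trees():
    return list(enumerate_space("T", 4))


@pytest.fixture(scope="session")
def t5_trees():
    return list(enumerate_space("T", 5))


@pytest.fixture(scope="session")
def bt4_trees():
    return list(enumerate_space("BT", 4))


@pytest.fixture(scope="session")
def bt5_trees():
    return list(enumerate_space("BT", 5))


@pytest.fixture(scope="session")
def bt6_trees():
    return list(enumerate_space("BT", 6))


@pytest.fixture(scope="session")
def bt6_correlations():
    return exhaustive_correlations("BT", 6)


@pytest.fixture(scope="session")
def t6_correlations():
    return exhaustive_correlations("T", 6)
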