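import pytest
from hypothesis import settings

from ccdtree import parse_trees, tally

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")

# Worked example: seven-tree posterior sample on five taxa in which the root
# clade is split three ways and ABC two ways; the induced CCD1 displays six
# topologies with probabilities 12/49, 9/49, 8/49, 8/49, 6/49, 6/49.
SEVEN_TREE_NEWICKS = (
    ["(((A,B),C),(D,E));"] * 3
    + ["(((A,(B,C)),D),E);"] * 2
    + ["(((A,(B,C)),E),D);"] * 2
)

# Two-tree sample on four taxa in which AB, CD and ABCD are all observed but
# the split AB|CD is not: clade-based expansion adds it, split-based does not.
CLADE_EXPANSION_NEWICKS = ["(((A,B),C),D);", "(((C,D),A),B);"]


def sample_from(newicks):
    return parse_trees("\n".join(newicks), format="newick", burnin_fraction=0.0)


@pytest.fixture(scope="session")
def seven_tree_sample():
    return sample_from(SEVEN_TREE_NEWICKS)


@pytest.fixture(scope="session")
def seven_tree_table(seven_tree_sample):
    return tally(seven_tree_sample)


@pytest.fixture(scope="session")
def expansion_sample():
    return sample_from(CLADE_EXPANSION_NEWICKS)


@pytest.fixture(scope="session")
def expansion_table(expansion_sample):
    return tally(expansion_sample)
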