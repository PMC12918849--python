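import random

import numpy as np
import pytest

from phylodeco import msc
from phylodeco.simulate import fixture_tree
from phylodeco.trees import Node, PhyloTree, parse_newick


@pytest.fixture(scope="session")
def fixture17():
    return fixture_tree()


@pytest.fixture
def triplet_tree():
    """3-taxon species tree with internal branch of 1 coalescent unit."""
    return parse_newick("((A:2,B:2):1,C:3);")


@pytest.fixture(scope="session")
def quartet_network():
    """4-taxon network: lineage A jumps to C's pendant edge at t=0.5."""
    sp = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")

    def make(gamma):
        return msc.ReticNetwork(
            sp, [msc.Reticulation(frozenset({"A"}), frozenset({"C"}), 0.5, gamma)]
        )

    return make


def random_rooted_tree(labels, rng, bl=1.0):
    """Uniform random rooted binary topology via sequential pair joins."""
    nodes = [Node(label=l, length=bl) for l in labels]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        j = rng.randrange(len(nodes) - 1)
        if j >= i:
            j += 1
        p = Node(length=bl)
        p.add_child(nodes[i])
        p.add_child(nodes[j])
        for k in sorted((i, j), reverse=True):
            nodes.pop(k)
        nodes.append(p)
    nodes[0].length = None
    return PhyloTree(nodes[0])


def balanced_ultrametric(levels, bl=1.0):
    counter = [0]

    def rec(d):
        if d == 0:
            counter[0] += 1
            return f"s{counter[0]}:{bl}"
        return f"({rec(d - 1)},{rec(d - 1)}):{bl}"

    return parse_newick(rec(levels) + ";")
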