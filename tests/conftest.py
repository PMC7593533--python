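import pytest
from fractions import Fraction

from phylocircuit import FixtureSpec, PhyloNetwork, random_1nested


def square_network(cycle_weights=(1, 1, 1, 1), leaf_weights=(1, 1, 1, 1), labels=(1, 2, 3, 4)):
    """4-cycle with one pendant leaf per cycle node, leaves placed in the
    given order around the cycle."""
    cyc = ["a", "b", "c", "d"]
    edges = []
    for i in range(4):
        edges.append((cyc[i], cyc[(i + 1) % 4], Fraction(cycle_weights[i])))
        edges.append((labels[i], cyc[i], Fraction(leaf_weights[i])))
    return PhyloNetwork.from_edges(edges)


def quartet_tree(weights=(1, 1, 1, 1, 1)):
    """Binary quartet tree with split 12|34; weights: leaf1, leaf2, internal,
    leaf3, leaf4."""
    w = [Fraction(x) for x in weights]
    return PhyloNetwork.from_edges(
        [(1, "u", w[0]), (2, "u", w[1]), ("u", "v", w[2]), (3, "v", w[3]), (4, "v", w[4])]
    )


def star_tree(weights):
    return PhyloNetwork.from_edges(
        [(i + 1, "hub", Fraction(w)) for i, w in enumerate(weights)]
    )


def cycle_network(weights, leaf_weights=None):
    """m-cycle with a pendant leaf on every cycle node, leaves 1..m in cycle
    order."""
    m = len(weights)
    leaf_weights = leaf_weights or [1] * m
    edges = []
    for i in range(m):
        edges.append((f"c{i}", f"c{(i + 1) % m}", Fraction(weights[i])))
        edges.append((i + 1, f"c{i}", Fraction(leaf_weights[i])))
    return PhyloNetwork.from_edges(edges)


@pytest.fixture(scope="session")
def fixture_pool():
    """200 seeded random weighted binary triangle-free 1-nested networks,
    n = 5..8, each containing at least one cycle."""
    nets = []
    for n in (5, 6, 7, 8):
        for seed in range(50):
            nets.append(random_1nested(FixtureSpec(n=n, seed=seed)))
    return nets


@pytest.fixture(scope="session")
def two_nested_6():
    """All binary triangle-free strictly 2-nested networks on 6 leaves."""
    from phylocircuit import enumerate_2nested

    return enumerate_2nested(6)
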