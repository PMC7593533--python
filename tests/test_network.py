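import itertools
from fractions import Fraction

import networkx as nx
import pytest

import phylocircuit as pc
from phylocircuit.network import CYCLE, THETA

from conftest import cycle_network, quartet_tree, square_network, star_tree


class TestValidation:
    def test_two_leaf_edge_is_valid(self):
        net = pc.PhyloNetwork.from_edges([(1, 2, Fraction(3))])
        assert net.n == 2

    def test_square_with_pendants_is_valid(self):
        net = square_network()
        assert net.n == 4 and net.graph.number_of_edges() == 8

    def test_degree_two_internal_node_rejected(self):
        g = nx.Graph()
        g.add_edge("leaf1", "b", weight=1)
        g.add_edge("b", "leaf2", weight=1)
        problems = pc.validate_network(g, {1: "leaf1", 2: "leaf2"})
        assert any("degree 2" in p for p in problems)
        with pytest.raises(pc.NetworkError):
            pc.PhyloNetwork(g, {1: "leaf1", 2: "leaf2"})

    def test_disconnected_and_negative_weight_reported(self):
        g = nx.Graph()
        g.add_edge("leaf1", "leaf2", weight=-1)
        g.add_edge("leaf3", "leaf4", weight=1)
        problems = pc.validate_network(
            g, {i: f"leaf{i}" for i in range(1, 5)}
        )
        assert any("not connected" in p for p in problems)
        assert any("negative weight" in p for p in problems)


class TestBridges:
    def test_every_tree_edge_is_a_bridge(self):
        t = quartet_tree()
        assert len(pc.find_bridges(t)) == t.graph.number_of_edges() == 5

    def test_square_has_only_trivial_leaf_bridges(self):
        bridges = pc.find_bridges(square_network())
        assert len(bridges) == 4 and all(b.is_trivial for b in bridges)

    def test_joining_edge_of_two_cycles_is_unique_nontrivial_bridge(self):
        edges = []
        for tag, leaves in (("p", (1, 2, 3)), ("q", (4, 5, 6))):
            cyc = [f"{tag}{i}" for i in range(4)]
            for i in range(4):
                edges.append((cyc[i], cyc[(i + 1) % 4], Fraction(1)))
            for lab, node in zip(leaves, cyc[:3]):
                edges.append((lab, node, Fraction(1)))
        edges.append(("p3", "q3", Fraction(1)))
        net = pc.PhyloNetwork.from_edges(edges)
        nontrivial = [b for b in pc.find_bridges(net) if not b.is_trivial]
        assert len(nontrivial) == 1
        assert {tuple(sorted((nontrivial[0].u, nontrivial[0].v)))} == {("p3", "q3")}


class TestBlocks:
    def test_tree_has_no_blocks(self):
        assert pc.cycle_blocks(quartet_tree()) == []

    def test_five_cycle_is_one_cycle_block(self):
        blocks = pc.cycle_blocks(cycle_network([1] * 5))
        assert len(blocks) == 1
        assert blocks[0].kind == CYCLE and len(blocks[0].edges) == 5

    def test_chorded_cycle_is_theta_with_edges_in_two_cycles(self):
        base = cycle_network([1] * 5)
        block = pc.cycle_blocks(base)[0]
        net = pc.insert_chord(base, block, (0, 2))
        blocks = pc.cycle_blocks(net)
        assert len(blocks) == 1 and blocks[0].kind == THETA
        # each theta edge lies in exactly 2 of the 3 simple cycles
        sub = net.graph.subgraph(blocks[0].nodes)
        cycles = [c for c in nx.simple_cycles(sub)]
        assert len(cycles) == 3
        for u, v in sub.edges():
            member = sum(
                1 for c in cycles if u in c and v in c and
                abs(c.index(u) - c.index(v)) in (1, len(c) - 1)
            )
            assert member == 2


class TestNestedness:
    def test_tree_is_level_zero(self):
        assert pc.nestedness_level(quartet_tree()).level == 0

    def test_two_cycles_joined_by_bridge_is_level_one(self):
        net = pc.random_1nested(pc.FixtureSpec(n=7, seed=11, min_cycles=2))
        nest = pc.nestedness_level(net)
        assert nest.level == 1 and nest.triangle_free

    def test_chorded_cycle_is_level_two(self):
        base = cycle_network([1] * 5)
        net = pc.insert_chord(base, pc.cycle_blocks(base)[0], (0, 2))
        assert pc.nestedness_level(net).level == 2

    def test_k33_is_beyond_level_two_but_triangle_free(self):
        nest = pc.nestedness_level(pc.k33_counterexample())
        assert nest.level == 3 and nest.triangle_free

    def test_triangle_detected(self):
        net = pc.PhyloNetwork.from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "a", 1),
             (1, "a", 1), (2, "b", 1), (3, "c", 1)]
        )
        assert not pc.nestedness_level(net).triangle_free


class TestBinary:
    def test_star_with_four_leaves_is_not_binary(self):
        assert not pc.is_binary(star_tree([1, 1, 1, 1]))

    def test_square_and_quartet_are_binary(self):
        assert pc.is_binary(square_network())
        assert pc.is_binary(quartet_tree())


def _sigma_brute_force(net):
    """Independent oracle: test every single edge and every pair of edges for
    being a 2-component cut, and collect the leaf bipartitions."""
    node_to_label = {v: k for k, v in net.leaves.items()}
    splits = set()
    all_edges = list(net.graph.edges())
    for r in (1, 2):
        for combo in itertools.combinations(all_edges, r):
            g = net.graph.copy()
            g.remove_edges_from(combo)
            comps = list(nx.connected_components(g))
            if len(comps) != 2:
                continue
            side = {node_to_label[x] for x in comps[0] if x in node_to_label}
            if side and len(side) < net.n:
                splits.add(pc.Split.of(side, set(net.leaves) - side))
    return splits


class TestSigma:
    def test_quartet_tree_sigma(self):
        system = pc.sigma_splits(quartet_tree())
        assert len(system) == 5
        assert pc.Split.of({1, 2}, {3, 4}) in system

    def test_square_displays_opposite_edge_pairs(self):
        system = pc.sigma_splits(square_network())
        nontrivial = system.nontrivial
        assert nontrivial == frozenset(
            {pc.Split.of({1, 2}, {3, 4}), pc.Split.of({1, 4}, {2, 3})}
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_sigma_matches_brute_force_cut_enumeration(self, seed):
        net = pc.random_1nested(pc.FixtureSpec(n=6, seed=seed))
        assert set(pc.sigma_splits(net).splits) == _sigma_brute_force(net)

    def test_sigma_contains_exactly_n_trivial_splits(self, fixture_pool):
        for net in fixture_pool[:20]:
            system = pc.sigma_splits(net)
            assert sum(1 for s in system if s.is_trivial) == net.n

    def test_sigma_raises_beyond_1nested(self):
        base = cycle_network([1] * 5)
        net = pc.insert_chord(base, pc.cycle_blocks(base)[0], (0, 2))
        with pytest.raises(pc.NetworkError):
            pc.sigma_splits(net)


class TestSplitEquivalence:
    def test_reflexive(self):
        net = square_network()
        assert pc.split_equivalent(net, net)

    def test_different_leaf_orders_of_square_not_equivalent(self):
        assert not pc.split_equivalent(
            square_network(labels=(1, 2, 3, 4)), square_network(labels=(1, 3, 2, 4))
        )

    def test_twisting_around_a_bridge_preserves_splits(self):
        # two quartet-like halves joined by a bridge; reflect one half
        a = pc.PhyloNetwork.from_edges(
            [(1, "u", 1), (2, "u", 1), ("u", "v", 1),
             ("v", "w", 1), (3, "w", 1), (4, "w", 1), ("v", 5, 1)]
        )
        b = pc.PhyloNetwork.from_edges(
            [(2, "u", 1), (1, "u", 1), ("u", "v", 1),
             ("v", "w", 1), (4, "w", 1), (3, "w", 1), ("v", 5, 1)]
        )
        assert pc.split_equivalent(a, b)


class TestConsistentOrders:
    def test_quartet_tree_has_two_canonical_order_classes(self):
        orders = pc.consistent_orders(quartet_tree())
        assert {tuple(o) for o in orders} == {(1, 2, 3, 4), (1, 2, 4, 3)}

    def test_square_has_exactly_one_order(self):
        orders = pc.consistent_orders(square_network())
        assert {tuple(o) for o in orders} == {(1, 2, 3, 4)}

    def test_orders_nonempty_for_1nested(self, fixture_pool):
        for net in fixture_pool[:30]:
            assert pc.consistent_orders(net)

    def test_bound_enforced(self):
        net = star_tree([1] * 10)
        with pytest.raises(ValueError):
            pc.consistent_orders(net, bound=9)


class TestCircularOrderCanonicalization:
    def test_rotation_and_reflection_collapse(self):
        base = pc.CircularOrder.of((1, 2, 3, 4, 5))
        rotated = pc.CircularOrder.of((3, 4, 5, 1, 2))
        reflected = pc.CircularOrder.of((1, 5, 4, 3, 2))
        assert base == rotated == reflected

    def test_contiguity_on_circle(self):
        order = pc.CircularOrder.of((1, 2, 3, 4, 5))
        assert order.is_contiguous(frozenset({5, 1, 2}))
        assert not order.is_contiguous(frozenset({1, 3}))
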