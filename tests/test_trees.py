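"""Tree model, Newick I/O, bipartitions, contraction, rootings."""

import random

import pytest

import coalphylo as cp
from coalphylo.trees import (
    edge_support,
    enumerate_unrooted_topologies,
    is_binary,
    leaf_labels,
    unrooted_copy,
)

from _oracles import compatibility_oracle


class TestParseNewick:
    def test_lengths_and_topology(self):
        t = cp.parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert leaf_labels(t) == {"A", "B", "C"}
        internal = [nd for nd in t.preorder_internal_node_iter() if nd.parent_node]
        assert len(internal) == 1 and internal[0].edge.length == 0.5

    def test_star_tree(self):
        t = cp.parse_newick("(A,B,C);")
        assert len(t.seed_node.child_nodes()) == 3
        assert cp.bipartitions(t) == set()

    def test_supports_unit_scale(self):
        t = cp.parse_newick("((A,B)0.9,(C,D)0.4);")
        sups = sorted(
            edge_support(nd)
            for nd in t.preorder_internal_node_iter()
            if nd.parent_node
        )
        assert sups == [0.4, 0.9]

    def test_supports_percent_scale_autodetected(self):
        t = cp.parse_newick("((A,B)90,(C,D)40);")
        sups = sorted(
            edge_support(nd)
            for nd in t.preorder_internal_node_iter()
            if nd.parent_node
        )
        assert sups == [0.4, 0.9]

    def test_malformed_raises(self):
        with pytest.raises(cp.NewickParseError):
            cp.parse_newick("((A,B),C;")

    def test_duplicate_leaf_raises(self):
        with pytest.raises(cp.NewickParseError, match="duplicate"):
            cp.parse_newick("((A,B),A);")


class TestWriteNewick:
    @pytest.mark.parametrize("seed", range(25))
    def test_round_trip_random_trees(self, seed):
        r = random.Random(seed)
        t = cp.random_binary_tree(
            [f"t{i}" for i in range(r.randint(4, 12))],
            r,
            rooted=bool(seed % 2),
            branch_length=lambda rr: round(rr.uniform(0.01, 2.0), 6),
        )
        back = cp.parse_newick(cp.write_newick(t))
        assert cp.same_topology(t, back)
        lens1 = sorted(
            e.length for e in t.preorder_edge_iter() if e.tail_node is not None
        )
        lens2 = sorted(
            e.length for e in back.preorder_edge_iter() if e.tail_node is not None
        )
        assert lens1 == pytest.approx(lens2, abs=1e-9)

    def test_supports_survive_round_trip(self):
        t = cp.parse_newick("((A,B)0.9,(C,D)0.4);")
        back = cp.parse_newick(cp.write_newick(t))
        assert cp.same_topology(t, back)
        sups = {
            edge_support(nd)
            for nd in back.preorder_internal_node_iter()
            if nd.parent_node
        }
        assert sups == {0.9, 0.4}


class TestBipartitions:
    def test_binary_17_leaf_tree_has_14_internal_edges(self, rng):
        t = cp.random_binary_tree([f"t{i:02d}" for i in range(17)], rng, rooted=False)
        assert len(cp.bipartitions(t)) == 14

    def test_single_internal_edge_quartet(self):
        t = cp.parse_newick("((A,B),(C,D));")
        (b,) = cp.bipartitions(t)
        assert {b.side, b.other_side} == {frozenset("AB"), frozenset("CD")}

    def test_rooted_and_unrooted_views_agree(self, rng):
        t = cp.random_binary_tree(list("ABCDEFG"), rng, rooted=True)
        assert cp.bipartitions(t) == cp.bipartitions(unrooted_copy(t))


class TestContractLowSupport:
    def _with_supports(self, newick):
        return cp.parse_newick(newick)

    def test_all_high_supports_identity(self):
        t = self._with_supports("((A,B)1.0,((C,D)1.0,E)1.0);")
        out = cp.contract_low_support(t, 0.75)
        assert cp.same_topology(out, t)

    def test_all_zero_supports_star(self):
        t = self._with_supports("((A,B)0.0,((C,D)0.0,E)0.0);")
        out = cp.contract_low_support(t, 0.75)
        assert cp.bipartitions(out) == set()

    def test_threshold_is_strict(self):
        # supports 0.9 / 0.75 / 0.74: only the edge strictly below 0.75 goes
        t = self._with_supports("((A,B)0.9,C,((D,E)0.75,F)0.74);")
        out = cp.contract_low_support(t, 0.75)
        kept = cp.bipartitions(out)
        assert cp.Bipartition(frozenset("AB"), leaf_labels(t)) in kept
        assert cp.Bipartition(frozenset("DE"), leaf_labels(t)) in kept
        assert cp.Bipartition(frozenset("DEF"), leaf_labels(t)) not in kept
        assert len(kept) == 2

    def test_contraction_never_adds_splits(self, rng):
        t = cp.random_binary_tree(list("ABCDEFGH"), rng, rooted=False)
        for nd in t.preorder_internal_node_iter():
            if nd.parent_node is not None:
                cp.trees.set_edge_support(nd, rng.random())
        full = cp.bipartitions(t)
        for theta in (0.0, 0.3, 0.75, 1.0):
            assert cp.bipartitions(cp.contract_low_support(t, theta)) <= full

    def test_missing_support_raises(self):
        t = cp.parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="support"):
            cp.contract_low_support(t, 0.75)


class TestAllRootings:
    def test_quartet_has_five_rootings(self):
        t = cp.parse_newick("((A,B),(C,D));")
        assert len(cp.all_rootings(t)) == 5

    def test_three_leaf_star(self):
        assert len(cp.all_rootings(cp.parse_newick("(A,B,C);"))) == 3

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_binary_tree_has_2n_minus_3_rootings(self, n, rng):
        t = cp.random_binary_tree([f"t{i}" for i in range(n)], rng, rooted=False)
        rootings = cp.all_rootings(t)
        assert len(rootings) == 2 * n - 3
        for r in rootings:
            assert r.is_rooted and is_binary(r, rooted=True)
            assert cp.same_topology(r, t)


class TestTreeFromBipartitions:
    def test_empty_set_gives_star(self):
        t = cp.tree_from_bipartitions("ABCDE", [])
        assert cp.bipartitions(t) == set()
        assert leaf_labels(t) == set("ABCDE")

    def test_full_split_set_rebuilds_tree(self, rng):
        t = cp.random_binary_tree(list("ABCDEFG"), rng, rooted=False)
        rebuilt = cp.tree_from_bipartitions(leaf_labels(t), cp.bipartitions(t))
        assert cp.same_topology(rebuilt, t)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_subsets_display_exactly_those_splits(self, seed):
        r = random.Random(seed)
        t = cp.random_binary_tree(list("ABCDEFGH"), r, rooted=False)
        splits = list(cp.bipartitions(t))
        subset = [b for b in splits if r.random() < 0.5]
        built = cp.tree_from_bipartitions(leaf_labels(t), subset)
        assert cp.bipartitions(built) == set(subset)

    def test_incompatible_set_raises(self):
        leaves = set("ABCDE")
        b1 = cp.Bipartition(frozenset("BC"), leaves)
        b2 = cp.Bipartition(frozenset("CD"), leaves)
        with pytest.raises(ValueError, match="incompatible"):
            cp.tree_from_bipartitions(leaves, [b1, b2])


class TestCompatibility:
    def test_nested_sides_compatible(self):
        leaves = set("ABCDE")
        b = cp.Bipartition(frozenset("DE"), leaves)
        other = cp.Bipartition(frozenset("CDE"), leaves)
        assert cp.is_compatible(b, [other])

    def test_crossing_sides_incompatible(self):
        leaves = set("ABCDE")
        b = cp.Bipartition(frozenset("BC"), leaves)
        other = cp.Bipartition(frozenset("CD"), leaves)
        assert not cp.is_compatible(b, [other])

    def test_mismatched_leafsets_raise(self):
        b = cp.Bipartition(frozenset("CD"), set("ABCD"))
        other = cp.Bipartition(frozenset("DE"), set("ABCDE"))
        with pytest.raises(ValueError):
            cp.is_compatible(b, [other])

    def test_matches_tree_enumeration_oracle_on_5_taxa(self):
        leaves = set("ABCDE")
        all_splits = []
        for t in enumerate_unrooted_topologies(sorted(leaves)):
            all_splits.extend(cp.bipartitions(t))
        all_splits = sorted(set(all_splits), key=lambda b: tuple(sorted(b.side)))
        for b1 in all_splits:
            for b2 in all_splits:
                assert cp.is_compatible(b1, [b2]) == compatibility_oracle(
                    b1, [b2], leaves
                )
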