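"""Gene-tree estimation: logdet, path distances, NJ, bootstrap, summaries."""

import itertools
import math
import random

import numpy as np
import pytest
from skbio import DistanceMatrix

import coalphylo as cp
from coalphylo.alignment import Alignment
from coalphylo.trees import edge_support


class TestLogdetDistance:
    def test_identical_sequences_have_zero_distance(self):
        aln = Alignment({"A": "ACGTACGTAC", "B": "ACGTACGTAC"})
        d = cp.logdet_distance(aln)
        assert d["A", "B"] == 0.0

    def test_symmetric_matrix(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"t{i}": "".join(rng.choice(list("ACGT-"), size=200)) for i in range(5)
        }
        d = cp.logdet_distance(Alignment(seqs))
        assert np.allclose(d.data, d.data.T)

    def test_consistent_under_jc(self):
        t = 0.3
        tree = cp.parse_newick(f"(A:0,B:{t});")
        tree.is_rooted = True
        aln, _ = cp.simulate_sequences(
            tree, cp.SubstitutionModel.jc(), cp.IndelModel.none(), 100000,
            np.random.default_rng(4),
        )
        d = cp.logdet_distance(aln)
        assert d["A", "B"] == pytest.approx(t, rel=0.02)

    def test_gapped_sites_excluded_pairwise(self):
        aln = Alignment({"A": "ACGT--ACGT", "B": "ACGTAAAC-T", "C": "ACGTAAACGT"})
        d = cp.logdet_distance(aln)
        assert d["A", "B"] == 0.0  # all shared ungapped sites agree

    def test_saturated_pair_capped_with_warning(self):
        # constant-base sequences make the divergence matrix singular
        aln = Alignment({"A": "A" * 50, "B": "C" * 50})
        with pytest.warns(UserWarning, match="saturation"):
            d = cp.logdet_distance(aln)
        assert d["A", "B"] == cp.genetrees.SATURATION_CAP

    def test_no_shared_sites_rejected(self):
        aln = Alignment({"A": "AC--", "B": "--GT"})
        with pytest.raises(ValueError, match="comparable"):
            cp.logdet_distance(aln)


class TestTreePathDistances:
    def test_cherry_distance_is_sum_of_lengths(self):
        t = cp.parse_newick("(A:1,B:2,C:5);")
        d = cp.tree_path_distances(t)
        assert d["A", "B"] == pytest.approx(3.0)

    def test_ultrametric_tree_gives_ultrametric_matrix(self):
        t = cp.generate_species_tree(8, seed=2)
        d = cp.tree_path_distances(t)
        for a, b, c in itertools.combinations(d.ids, 3):
            x, y, z = sorted([d[a, b], d[a, c], d[b, c]])
            assert z == pytest.approx(y, rel=1e-6)

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError):
            cp.tree_path_distances(cp.parse_newick("((A,B),C);"))


class TestNJTree:
    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_topology_from_additive_matrix(self, seed):
        r = random.Random(seed)
        t = cp.random_binary_tree(
            list("ABCDEF"), r, rooted=False,
            branch_length=lambda rr: rr.uniform(0.1, 1.0),
        )
        est = cp.nj_tree(cp.tree_path_distances(t))
        assert cp.same_topology(est, t)

    def test_quartet_matches_four_point_condition(self):
        r = random.Random(3)
        t = cp.random_binary_tree(
            list("ABCD"), r, rooted=False, branch_length=lambda rr: rr.uniform(0.2, 1.0)
        )
        d = cp.tree_path_distances(t)
        # the true quartet minimises the pair-sum (four-point condition)
        sums = {
            ("AB", "CD"): d["A", "B"] + d["C", "D"],
            ("AC", "BD"): d["A", "C"] + d["B", "D"],
            ("AD", "BC"): d["A", "D"] + d["B", "C"],
        }
        best = min(sums, key=sums.get)
        est = cp.nj_tree(d)
        (split,) = cp.bipartitions(est)
        assert {frozenset(best[0]), frozenset(best[1])} == {split.side, split.other_side}

    def test_taxon_order_invariance(self):
        r = random.Random(5)
        t = cp.random_binary_tree(
            list("ABCDEFG"), r, rooted=False, branch_length=lambda rr: rr.uniform(0.1, 1.0)
        )
        d = cp.tree_path_distances(t)
        perm = list(d.ids)[::-1]
        d2 = d.filter(perm)
        assert cp.same_topology(cp.nj_tree(d), cp.nj_tree(d2))

    def test_too_few_taxa_rejected(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]), list("ABC"))
        with pytest.raises(ValueError):
            cp.nj_tree(d)


class TestBootstrapSupport:
    def _signal_alignment(self, length=4000, seed=0):
        r = random.Random(seed)
        t = cp.random_binary_tree(
            list("ABCDEF"), r, rooted=False,
            branch_length=lambda rr: rr.uniform(0.2, 0.6),
        )
        rooted = cp.all_rootings(t)[0]
        aln, _ = cp.simulate_sequences(
            rooted, cp.SubstitutionModel.jc(), cp.IndelModel.none(), length,
            np.random.default_rng(seed),
        )
        return t, aln

    def test_high_signal_gives_high_supports(self):
        t, aln = self._signal_alignment()
        est = cp.bootstrap_support(aln, 30, np.random.default_rng(1))
        sups = [
            edge_support(nd)
            for nd in est.preorder_internal_node_iter()
            if nd.parent_node is not None
        ]
        assert sups and all(s >= 0.95 for s in sups)
        assert cp.same_topology(est, t)

    def test_supports_lie_in_unit_interval_and_deterministic(self):
        _, aln = self._signal_alignment(length=120, seed=2)
        e1 = cp.bootstrap_support(aln, 20, np.random.default_rng(9))
        e2 = cp.bootstrap_support(aln, 20, np.random.default_rng(9))
        s1 = sorted(
            edge_support(nd)
            for nd in e1.preorder_internal_node_iter()
            if nd.parent_node is not None
        )
        s2 = sorted(
            edge_support(nd)
            for nd in e2.preorder_internal_node_iter()
            if nd.parent_node is not None
        )
        assert s1 == s2
        assert all(0.0 <= s <= 1.0 for s in s1)

    def test_supports_grow_with_sequence_length(self):
        means = []
        for length in (150, 3000):
            _, aln = self._signal_alignment(length=length, seed=6)
            est = cp.bootstrap_support(aln, 25, np.random.default_rng(3))
            sups = [
                edge_support(nd)
                for nd in est.preorder_internal_node_iter()
                if nd.parent_node is not None
            ]
            means.append(sum(sups) / len(sups))
        assert means[1] >= means[0]


class TestPointEstimates:
    def test_single_tree_sample(self, rng):
        t = cp.random_binary_tree(list("ABCDE"), rng, rooted=False)
        for kind in ("majority", "map"):
            assert cp.same_topology(cp.point_estimates([t], kind), t)

    def test_map_is_modal_topology(self, rng):
        x = cp.random_binary_tree(list("ABCDE"), rng, rooted=False)
        y = cp.random_binary_tree(list("ABCDE"), rng, rooted=False)
        while cp.same_topology(x, y):
            y = cp.random_binary_tree(list("ABCDE"), rng, rooted=False)
        sample = [x, x, x, y, y]
        assert cp.same_topology(cp.point_estimates(sample, "map"), x)

    def test_majority_of_even_split_is_unresolved(self, rng):
        x = cp.parse_newick("((A,B),(C,D),E);")
        y = cp.parse_newick("((A,C),(B,D),E);")
        cons = cp.point_estimates([x, y], "majority")
        assert cp.bipartitions(cons) == set()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cp.point_estimates([], "map")
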