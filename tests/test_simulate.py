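"""Species-tree generation, branch scaling/perturbation, and the
multispecies coalescent simulator."""

import math
import random

import pytest

import coalphylo as cp
from coalphylo.trees import leaf_labels


def node_ages(tree):
    depth = {}
    for nd in tree.preorder_node_iter():
        depth[nd] = 0.0 if nd.parent_node is None else depth[nd.parent_node] + nd.edge.length
    h = max(depth[lf] for lf in tree.leaf_node_iter())
    return {nd: h - d for nd, d in depth.items()}


def total_treelength(tree):
    return sum(
        e.length
        for e in tree.preorder_edge_iter()
        if e.length is not None
    )


class TestGenerateSpeciesTree:
    @pytest.mark.parametrize("n", [4, 8, 15])
    def test_leaf_count_and_ultrametricity(self, n):
        for seed in range(5):
            t = cp.generate_species_tree(n, seed=seed)
            assert len(t.leaf_nodes()) == n
            ages = node_ages(t)
            for lf in t.leaf_node_iter():
                assert ages[lf] == pytest.approx(0.0, abs=1e-8)

    def test_deterministic_given_seed(self):
        t1 = cp.generate_species_tree(10, seed=5)
        t2 = cp.generate_species_tree(10, seed=5)
        assert cp.write_newick(t1) == cp.write_newick(t2)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            cp.generate_species_tree(3)
        with pytest.raises(ValueError):
            cp.generate_species_tree(6, birth_rate=0.5, death_rate=0.5)


class TestScaleBranches:
    def test_identity_and_linear_scaling(self, rng):
        t = cp.generate_species_tree(8, seed=3)
        same = cp.scale_branches(t, 1.0)
        assert total_treelength(same) == pytest.approx(total_treelength(t))
        scaled = cp.scale_branches(t, 0.05)
        assert total_treelength(scaled) == pytest.approx(0.05 * total_treelength(t))
        assert cp.same_topology(scaled, t, rooted=True)

    def test_unit_edge_scales_to_factor(self):
        t = cp.parse_newick("((A:1,B:1):1,C:2);")
        scaled = cp.scale_branches(t, 0.05)
        lengths = sorted(
            e.length for e in scaled.preorder_edge_iter() if e.tail_node is not None
        )
        assert lengths == pytest.approx([0.05, 0.05, 0.05, 0.1])

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError):
            cp.scale_branches(cp.parse_newick("((A,B),C);"), 0.5)


class TestPerturbBranchLengths:
    def test_total_treelength_preserved_exactly(self, rng):
        t = cp.generate_species_tree(10, seed=1)
        p = cp.perturb_branch_lengths(t, rng, sigma=0.5)
        assert total_treelength(p) == pytest.approx(total_treelength(t), rel=1e-12)

    def test_point_mass_distribution_is_identity(self, rng):
        t = cp.generate_species_tree(8, seed=2)
        p = cp.perturb_branch_lengths(t, rng, distribution=lambda r: 1.0)
        l1 = sorted(e.length for e in t.preorder_edge_iter() if e.length)
        l2 = sorted(e.length for e in p.preorder_edge_iter() if e.length)
        assert l1 == pytest.approx(l2)

    def test_topology_unchanged_across_seeds(self):
        t = cp.generate_species_tree(9, seed=4)
        for seed in range(30):
            p = cp.perturb_branch_lengths(t, random.Random(seed), sigma=0.8)
            assert cp.same_topology(p, t, rooted=True)

    def test_lognormal_mean_one_family(self):
        draw = cp.simulate.lognormal_mean_one(0.6)
        r = random.Random(0)
        mean = sum(draw(r) for _ in range(200000)) / 200000
        assert mean == pytest.approx(1.0, abs=0.01)


class TestMscGeneTree:
    def test_two_species_divergence_mean_is_tau_plus_one(self):
        # pairwise coalescence waits Exp(1) beyond the species divergence
        tau = 2.0
        sp = cp.parse_newick(f"(A:{tau},B:{tau});")
        sp.is_rooted = True
        r = random.Random(123)
        n = 6000
        tot = 0.0
        for _ in range(n):
            g = cp.simulate_msc_gene_tree(sp, r)
            tot += node_ages(g)[g.seed_node]
        mean = tot / n
        se = 1.0 / math.sqrt(n)  # Exp(1) has unit variance
        assert abs(mean - (tau + 1.0)) < 3 * se

    def test_three_taxon_concordance_matches_closed_form(self):
        # concordance probability 1 - (2/3) exp(-T) for internal branch T
        T = 1.0
        sp = cp.parse_newick(f"((A:1,B:1):{T},C:{1 + T});")
        sp.is_rooted = True
        r = random.Random(7)
        n = 4000
        hits = sum(
            cp.same_topology(cp.simulate_msc_gene_tree(sp, r), sp, rooted=True)
            for _ in range(n)
        )
        p_hat = hits / n
        p = 1 - (2 / 3) * math.exp(-T)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(p_hat - p) < 3.5 * se

    def test_long_branch_limit_has_no_discord(self):
        sp = cp.parse_newick("((A:1,B:1):50,C:51);")
        sp.is_rooted = True
        r = random.Random(9)
        hits = sum(
            cp.same_topology(cp.simulate_msc_gene_tree(sp, r), sp, rooted=True)
            for _ in range(2000)
        )
        assert hits / 2000 >= 0.999

    def test_coalescence_never_predates_speciation(self, rng):
        sp = cp.generate_species_tree(8, seed=6)
        sp_scaled = cp.scale_branches(sp, 0.3)
        s_ages = node_ages(sp_scaled)
        cluster_age = {
            frozenset(l.taxon.label for l in nd.leaf_iter()): s_ages[nd]
            for nd in sp_scaled.preorder_node_iter()
        }
        for _ in range(20):
            g = cp.simulate_msc_gene_tree(sp_scaled, rng)
            g_ages = node_ages(g)
            for nd in g.preorder_internal_node_iter():
                leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
                # age of the species LCA of this gene clade
                lca_age = min(
                    a for cl, a in cluster_age.items() if leaves <= cl
                )
                assert g_ages[nd] >= lca_age - 1e-9

    def test_missing_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            cp.simulate_msc_gene_tree(cp.parse_newick("((A,B),C);"), rng)


class TestGenerateDataset:
    def test_noils_gene_trees_share_species_topology(self):
        cfg = cp.ExperimentConfig(
            n_taxa=8, n_genes=6, mode="noils", root_length=40, seed=11
        )
        bundle = cp.generate_dataset(cfg)
        for g in bundle.gene_trees:
            assert cp.same_topology(g, bundle.species_tree, rooted=True)
        # half verbatim, half perturbed but rescaled to equal treelength
        totals = [total_treelength(g) for g in bundle.gene_trees]
        assert all(t == pytest.approx(totals[0]) for t in totals)

    def test_ils_mode_counts_and_units(self):
        cfg = cp.ExperimentConfig(
            n_taxa=6, n_genes=5, mode="ils", branch_scale=0.05, root_length=30, seed=3
        )
        bundle = cp.generate_dataset(cfg)
        assert len(bundle.gene_trees) == 5
        assert len(bundle.alignments) == 5
        assert bundle.coalescent_species_tree is not None
        assert leaf_labels(bundle.gene_trees[0]) == leaf_labels(bundle.species_tree)

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = cp.ExperimentConfig(n_taxa=6, n_genes=3, mode="ils", root_length=50, seed=21)
        for sub in ("a", "b"):
            cp.write_dataset(cp.generate_dataset(cfg), tmp_path / sub)
        for name in [p.name for p in (tmp_path / "a").iterdir()]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
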