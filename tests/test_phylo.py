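"""Tests of the framework tree, continuous parsimony, CI/RI, K and lambda."""

import subprocess
import sys
import textwrap

import dendropy
import numpy as np
import pytest

from fruitsignals.phylo import (
    blomberg_k,
    ci_ri,
    pagel_lambda,
    parsimony_steps_continuous,
    phylo_covariance,
    signal_table,
    tree_from_taxonomy,
)
from fruitsignals.synth import simulate_trait_on_tree

from .conftest import lp_parsimony_steps, random_yule_tree


def newick(text: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = True
    return tree


class TestTreeFromTaxonomy:
    def test_community_tree_has_all_tips(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        assert len(tree.leaf_nodes()) == 56

    def test_congeners_share_the_genus_node(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        strychnos = [
            leaf for leaf in tree.leaf_node_iter()
            if leaf.taxon.label.startswith("Strychnos")
        ]
        assert len(strychnos) == 5
        mrca = tree.mrca(taxa=[leaf.taxon for leaf in strychnos])
        assert len(mrca.leaf_nodes()) == 5  # genus node holds only Strychnos

    def test_unknown_species_attach_at_root(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label.startswith("UK "):
                assert leaf.parent_node is tree.seed_node

    def test_unit_branch_lengths(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length == 1.0

    def test_duplicate_species_rejected(self, table1_records):
        with pytest.raises(ValueError, match="duplicate"):
            tree_from_taxonomy(list(table1_records) + [table1_records[0]])

    def test_newick_round_trip(self, table1_records, tmp_path):
        from fruitsignals.io import read_tree, write_tree

        tree = tree_from_taxonomy(table1_records)
        path = tmp_path / "tree.nwk"
        write_tree(tree, path)
        again = read_tree(path)
        write_tree(again, tmp_path / "tree2.nwk")
        assert (tmp_path / "tree.nwk").read_text() == (tmp_path / "tree2.nwk").read_text()


class TestContinuousParsimony:
    def test_single_edge(self):
        assert parsimony_steps_continuous(
            newick("(A:1,B:1);"), {"A": 1.0, "B": 4.0}
        ) == pytest.approx(3.0)

    def test_star_median(self):
        # optimal internal value is the median
        assert parsimony_steps_continuous(
            newick("(A:1,B:1,C:1);"), {"A": 1.0, "B": 2.0, "C": 3.0}
        ) == pytest.approx(2.0)

    def test_matches_lp_oracle_on_random_trees(self):
        rng = np.random.default_rng(17)
        for rep in range(15):
            tree = random_yule_tree(int(rng.integers(4, 9)), seed=rep)
            trait = {
                leaf.taxon.label: float(rng.normal())
                for leaf in tree.leaf_node_iter()
            }
            mine = parsimony_steps_continuous(tree, trait)
            oracle = lp_parsimony_steps(tree, trait)
            assert abs(mine - oracle) < 1e-9

    def test_polytomies_handled_natively(self):
        tree = newick("((A:1,B:1,C:1):1,(D:1,E:1):1);")
        trait = {"A": 0.0, "B": 1.0, "C": 5.0, "D": 2.0, "E": 2.0}
        assert parsimony_steps_continuous(tree, trait) == pytest.approx(
            lp_parsimony_steps(tree, trait), abs=1e-9
        )

    def test_steps_scale_with_trait(self):
        tree = random_yule_tree(8, seed=3)
        rng = np.random.default_rng(1)
        trait = {l.taxon.label: float(rng.normal()) for l in tree.leaf_node_iter()}
        scaled = {k: 3.5 * v - 2.0 for k, v in trait.items()}
        assert parsimony_steps_continuous(tree, scaled) == pytest.approx(
            3.5 * parsimony_steps_continuous(tree, trait)
        )

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            parsimony_steps_continuous(newick("(A:1,B:1);"), {"A": 1.0})


class TestConsistencyRetention:
    def test_clade_perfect_character(self):
        tree = newick("((A:1,B:1):1,(C:1,D:1):1);")
        ci, ri = ci_ri(tree, {"A": 0.0, "B": 0.0, "C": 1.0, "D": 1.0})
        assert ci == pytest.approx(1.0)
        assert ri == pytest.approx(1.0)

    def test_star_tree_has_zero_retention(self):
        tree = newick("(A:1,B:1,C:1,D:1);")
        ci, ri = ci_ri(tree, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        assert ri == pytest.approx(0.0)
        assert ci == pytest.approx(3.0 / 4.0)

    def test_community_voc_shows_extensive_homoplasy(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        trait = {r.species: r.voc_index for r in table1_records}
        ci, ri = ci_ri(tree, trait)
        assert 0.02 < ci < 0.5  # same order as the published 0.180
        assert 0.0 <= ri < 0.6

    def test_constant_trait_rejected(self):
        tree = newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="constant"):
            ci_ri(tree, {"A": 1.0, "B": 1.0, "C": 1.0})


class TestBlombergK:
    def test_white_noise_k_well_below_one(self, yule_tree_50):
        ks = [
            blomberg_k(
                yule_tree_50,
                simulate_trait_on_tree(yule_tree_50, "white_noise", seed=500 + i),
                n_perm=10,
                seed=i,
            )[0]
            for i in range(20)
        ]
        assert np.mean(ks) < 0.4

    def test_brownian_k_near_one(self, yule_tree_50):
        ks = [
            blomberg_k(
                yule_tree_50,
                simulate_trait_on_tree(yule_tree_50, "brownian", seed=100 + i),
                n_perm=10,
                seed=i,
            )[0]
            for i in range(40)
        ]
        assert 0.8 < np.mean(ks) < 1.2

    def test_affine_invariance(self, yule_tree_50):
        trait = simulate_trait_on_tree(yule_tree_50, "brownian", seed=3)
        shifted = {k: -2.5 * v + 7.0 for k, v in trait.items()}
        k1, p1 = blomberg_k(yule_tree_50, trait, n_perm=99, seed=0)
        k2, p2 = blomberg_k(yule_tree_50, shifted, n_perm=99, seed=0)
        assert k1 == pytest.approx(k2, rel=1e-9)
        assert p1 == p2

    def test_too_few_tips(self):
        tree = newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="tips"):
            blomberg_k(tree, {"A": 1.0, "B": 2.0, "C": 3.0}, n_perm=10, seed=0)


class TestPagelLambda:
    def test_brownian_recovers_high_lambda(self, yule_tree_50):
        lams = [
            pagel_lambda(
                yule_tree_50, simulate_trait_on_tree(yule_tree_50, "brownian",
                                                     seed=200 + i)
            )[0]
            for i in range(20)
        ]
        assert np.median(lams) >= 0.8

    def test_white_noise_recovers_zero_lambda(self, yule_tree_50):
        lams = [
            pagel_lambda(
                yule_tree_50, simulate_trait_on_tree(yule_tree_50, "white_noise",
                                                     seed=300 + i)
            )[0]
            for i in range(20)
        ]
        assert np.median(lams) <= 0.2

    def test_lrt_statistic_nonnegative(self, yule_tree_50):
        from fruitsignals.phylo import _lambda_loglik

        C, labels = phylo_covariance(yule_tree_50)
        for seed in range(5):
            trait = simulate_trait_on_tree(yule_tree_50, "white_noise", seed=seed)
            lam, logl, p = pagel_lambda(yule_tree_50, trait)
            x = np.asarray([trait[l] for l in labels])
            assert logl >= _lambda_loglik(0.0, C, x) - 1e-9
            assert 0.0 <= p <= 1.0

    def test_affine_invariance(self, yule_tree_50):
        trait = simulate_trait_on_tree(yule_tree_50, "brownian", seed=8)
        shifted = {k: 0.1 * v - 40.0 for k, v in trait.items()}
        lam1, _, p1 = pagel_lambda(yule_tree_50, trait)
        lam2, _, p2 = pagel_lambda(yule_tree_50, shifted)
        assert lam1 == pytest.approx(lam2, abs=1e-5)
        assert p1 == pytest.approx(p2, abs=1e-6)


class TestAgainstPhytools:
    """Independent cross-check of K and lambda against R phytools."""

    def test_k_and_lambda_match_reference(self, tmp_path):
        tree = random_yule_tree(25, seed=9)
        trait = simulate_trait_on_tree(tree, "lambda", lam=0.6, seed=4)
        from fruitsignals.io import write_tree

        write_tree(tree, tmp_path / "t.nwk")
        with open(tmp_path / "x.csv", "w") as fh:
            fh.write("species,x\n")
            for k, v in trait.items():
                fh.write(f"{k},{v}\n")
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(phytools))
            tree <- read.tree("{tmp_path}/t.nwk")
            d <- read.csv("{tmp_path}/x.csv")
            x <- setNames(d$x, d$species)
            k <- phylosig(tree, x, method="K")
            l <- phylosig(tree, x, method="lambda", test=TRUE)
            cat(sprintf("%.10f %.10f %.6f", as.numeric(k), l$lambda, l$logL))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        k_ref, lam_ref, logl_ref = map(float, out.stdout.split())
        k, _ = blomberg_k(tree, trait, n_perm=10, seed=0)
        lam, logl, _ = pagel_lambda(tree, trait)
        assert k == pytest.approx(k_ref, rel=1e-6)
        assert lam == pytest.approx(lam_ref, abs=0.01)
        assert logl == pytest.approx(logl_ref, abs=0.01)


class TestSignalTable:
    def test_community_signal_statistics_valid(self, table1_records):
        tree = tree_from_taxonomy(table1_records)
        stats = signal_table(tree, table1_records, n_perm=99, seed=0)
        assert [s.trait for s in stats] == ["voc_index", "uv", "blue", "green", "red"]
        for s in stats:
            assert 0.0 < s.ci <= 1.0
            assert s.k >= 0.0
            assert 0.0 <= s.lam <= 1.0
            assert 0.0 <= s.k_p <= 1.0 and 0.0 <= s.lam_p <= 1.0
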