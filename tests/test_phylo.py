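import math
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import kstest

from thermobias import phylo, synthetic


class TestParseNewick:
    def test_basic_tree(self):
        phy = phylo.parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(phy.leaf_labels) == ["A", "B", "C"]
        assert not phy.has_polytomy

    def test_polytomy_flagged(self):
        phy = phylo.parse_newick("((A:1,B:1,C:1):1,D:1);")
        assert phy.has_polytomy

    def test_missing_branch_length_rejected(self):
        with pytest.raises(phylo.NewickError):
            phylo.parse_newick("(A:1,B);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(phylo.NewickError):
            phylo.parse_newick("((A:1,B:1):1;")

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(phylo.NewickError, match="duplicate"):
            phylo.parse_newick("(A:1,A:2);")


class TestZeroBranchAdjustment:
    def _lengths(self, phy):
        root = phy.tree.seed_node
        return sorted(
            n.edge.length for n in phy.tree.preorder_node_iter() if n is not root
        )

    def test_half_min_rule_reproduces_published_value(self):
        phy = phylo.parse_newick("((A:0,B:0.00006):0.1,C:0.2);")
        adj = phylo.adjust_zero_branches(phy)
        assert min(self._lengths(adj)) == pytest.approx(0.00003)

    def test_half_min_rule_generic(self):
        phy = phylo.parse_newick("(A:0,B:1.0);")
        assert self._lengths(phylo.adjust_zero_branches(phy)) == [0.5, 1.0]

    def test_no_zero_branches_is_identity(self):
        phy = phylo.parse_newick("((A:1,B:1):1,C:2);")
        assert self._lengths(phylo.adjust_zero_branches(phy)) == self._lengths(phy)

    def test_fixed_policy(self):
        phy = phylo.parse_newick("(A:0,B:1.0);")
        adj = phylo.adjust_zero_branches(phy, policy="fixed", value=0.1)
        assert self._lengths(adj) == [0.1, 1.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            phylo.adjust_zero_branches(phylo.parse_newick("(A:0,B:0);"))

    def test_polytomy_resolution_yields_bifurcating_adjusted_tree(self):
        phy = phylo.parse_newick("((A:1,B:1,C:1):1,D:1);")
        res = phylo.resolve_polytomies(phy)
        cs = phylo.independent_contrasts(res, {"A": 1, "B": 2, "C": 3, "D": 4})
        assert len(cs) == 3


class TestIndependentContrasts:
    def test_two_leaf_closed_form(self):
        phy = phylo.parse_newick("(A:1,B:1);")
        cs = phylo.independent_contrasts(phy, {"A": 2, "B": 0})
        assert cs.values == pytest.approx([2 / math.sqrt(2)])

    def test_three_leaf_hand_computation(self):
        # node (A,B): contrast 2/sqrt(2); value 2; branch 1 + 1*1/2 = 1.5
        # root: (2-0)/sqrt(1.5+2)
        phy = phylo.parse_newick("((A:1,B:1):1,C:2);")
        cs = phylo.independent_contrasts(phy, {"A": 3, "B": 1, "C": 0})
        assert cs.values == pytest.approx([1.4142135, 1.0690449], abs=1e-6)

    def test_four_leaf_hand_computation(self):
        # (A,B): (4-1)/sqrt(3); value 3; extension 2/3
        # (C,D): (3+1)/sqrt(2); value 1; extension 1/2
        # root:  (3-1)/sqrt(5/3 + 5/2)
        phy = phylo.parse_newick("((A:1,B:2):1,(C:1,D:1):2);")
        cs = phylo.independent_contrasts(phy, {"A": 4, "B": 1, "C": 3, "D": -1})
        expected = [3 / math.sqrt(3), 4 / math.sqrt(2), 2 / math.sqrt(5 / 3 + 5 / 2)]
        assert cs.values == pytest.approx(expected)

    def test_constant_trait_gives_zero_contrasts(self):
        phy = phylo.parse_newick("((A:1,B:2):1,(C:1,D:3):2);")
        cs = phylo.independent_contrasts(phy, dict.fromkeys("ABCD", 7.0))
        assert np.allclose(cs.values, 0.0)

    def test_contrast_count_is_leaves_minus_one(self):
        tree = synthetic.simulate_tree(33, seed=5)
        trait = synthetic.simulate_bm_trait(tree, 0, 1, seed=6)
        assert len(phylo.independent_contrasts(tree, trait)) == 32

    def test_missing_trait_names_the_species(self):
        phy = phylo.parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError, match="B"):
            phylo.independent_contrasts(phy, {"A": 1.0})

    def test_child_order_flips_sign_but_not_magnitude(self):
        t1 = phylo.parse_newick("((A:1,B:1):1,C:2);")
        t2 = phylo.parse_newick("((B:1,A:1):1,C:2);")
        trait = {"A": 3, "B": 1, "C": 0}
        c1 = phylo.independent_contrasts(t1, trait)
        c2 = phylo.independent_contrasts(t2, trait)
        assert np.allclose(np.abs(c1.values), np.abs(c2.values))
        assert c1.values[0] == -c2.values[0]

    def test_matches_ape_pic_oracle(self, tmp_path):
        """Cross-check against the independent R implementation (ape::pic)."""
        newick = "(((A:1.2,B:0.8):0.5,C:2.0):0.7,(D:1.5,E:0.9):1.1);"
        trait = {"A": 3.1, "B": 0.4, "C": -1.2, "D": 2.2, "E": 5.0}
        script = tmp_path / "pic.R"
        script.write_text(textwrap.dedent("""
            library(ape)
            tr <- read.tree(text="%s")
            x <- c(A=3.1, B=0.4, C=-1.2, D=2.2, E=5.0)
            cat(sort(abs(pic(x, tr))), sep="\\n")
        """ % newick))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        expected = sorted(float(v) for v in out.stdout.split())
        cs = phylo.independent_contrasts(phylo.parse_newick(newick), trait)
        assert sorted(np.abs(cs.values)) == pytest.approx(expected, rel=1e-6)


class TestContrastCorrelation:
    def _cs(self, values, ids=None):
        ids = ids or tuple(f"n{i}" for i in range(len(values)))
        return phylo.ContrastSet(tuple(ids), np.asarray(values, float), "t")

    def test_identical_vectors_correlate_perfectly(self):
        c = self._cs([1, 2, 3])
        assert phylo.contrast_correlation(c, c) == pytest.approx(1.0)

    def test_orthogonal_vectors_correlate_zero(self):
        assert phylo.contrast_correlation(self._cs([1, 0]), self._cs([0, 1])) == 0.0

    def test_invariant_to_pairwise_sign_flips(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r = phylo.contrast_correlation(self._cs(x), self._cs(y))
        s = rng.choice([-1, 1], size=12)
        r_flip = phylo.contrast_correlation(self._cs(x * s), self._cs(y * s))
        assert r_flip == pytest.approx(r)
        px, py = phylo.positivize(self._cs(x), self._cs(y))
        assert (px >= 0).all()
        assert phylo.contrast_correlation(self._cs(px), self._cs(py)) == pytest.approx(r)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            phylo.contrast_correlation(self._cs([0, 0]), self._cs([1, 2]))

    def test_node_order_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phylo.contrast_correlation(
                self._cs([1, 2], ids=("a", "b")), self._cs([1, 2], ids=("b", "a"))
            )


class TestRandomization:
    def _pair(self, rng, n=10):
        ids = tuple(f"n{i}" for i in range(n))
        cx = phylo.ContrastSet(ids, rng.normal(size=n), "x")
        cy = phylo.ContrastSet(ids, rng.normal(size=n), "y")
        return cx, cy

    def test_estimator_arithmetic(self):
        assert phylo.exceedance_pvalue(498, 9999) == pytest.approx(499 / 10000)
        assert phylo.exceedance_pvalue(0, 9999) == pytest.approx(1 / 10000)
        assert phylo.exceedance_pvalue(9999, 9999) == 1.0

    def test_p_respects_bounds(self, rng):
        for _ in range(10):
            cx, cy = self._pair(rng)
            res = phylo.randomization_pvalue(cx, cy, n_permutations=99, seed=1)
            assert 1 / 100 <= res.pvalue <= 1.0
            assert res.pvalue == pytest.approx((res.exceedances + 1) / 100)

    def test_perfect_association_hits_lower_bound(self):
        ids = tuple(f"n{i}" for i in range(8))
        x = np.arange(1.0, 9.0)
        cx = phylo.ContrastSet(ids, x, "x")
        cy = phylo.ContrastSet(ids, x * 2, "y")
        res = phylo.randomization_pvalue(cx, cy, n_permutations=199, seed=0)
        assert res.pvalue <= 2 / 200  # identity permutations can also hit R_obs

    def test_seed_reproducibility(self, rng):
        cx, cy = self._pair(rng)
        a = phylo.randomization_pvalue(cx, cy, n_permutations=199, seed=7)
        b = phylo.randomization_pvalue(cx, cy, n_permutations=199, seed=7)
        assert a == b

    def test_null_p_distribution_is_uniform(self):
        # Monte-Carlo calibration: independent contrast vectors must give a
        # p that is uniform on {i/200}
        pvals = []
        master = np.random.default_rng(2024)
        for _ in range(300):
            cx, cy = self._pair(master, n=10)
            pvals.append(
                phylo.randomization_pvalue(
                    cx, cy, n_permutations=199, seed=int(master.integers(2**31))
                ).pvalue
            )
        assert abs(np.mean(pvals) - 0.5) < 0.06
        assert kstest(pvals, "uniform").pvalue > 0.001


class TestPerAAProfile:
    def test_confounded_clade_attenuates_after_contrasts(self):
        panel = synthetic.simulate_confounded_panel(seed=0)
        prof = phylo.per_aa_temperature_profile(
            panel.proteomes, panel.traits, tree=panel.tree
        )
        row = prof.set_index("amino_acid").loc["E"]
        assert row["p"] < 0.05
        assert row["p_comp"] > 0.05

    def test_shuffled_trait_mostly_non_significant(self):
        panel = synthetic.simulate_confounded_panel(seed=3)
        rng = np.random.default_rng(9)
        traits = panel.traits.copy()
        traits["temperature"] = rng.permutation(traits["temperature"].to_numpy())
        prof = phylo.per_aa_temperature_profile(panel.proteomes, traits, tree=panel.tree)
        assert (prof["p"] < 0.05).mean() < 0.25
        assert (prof["p_comp"] < 0.05).mean() < 0.25

    def test_two_species_insufficient(self, small_panel):
        two = {s: small_panel.proteomes[s] for s in list(small_panel.proteomes)[:2]}
        with pytest.raises(ValueError):
            phylo.per_aa_temperature_profile(two, small_panel.traits)

    def test_tree_species_mismatch_listed(self, small_panel):
        tree = synthetic.simulate_tree(4, seed=0)  # wrong leaf set
        with pytest.raises(ValueError, match="mismatch"):
            phylo.per_aa_temperature_profile(
                small_panel.proteomes, small_panel.traits, tree=tree
            )


def test_bm_contrast_variance_recovers_sigma2():
    tree = synthetic.simulate_tree(200, seed=11)
    trait = synthetic.simulate_bm_trait(tree, 0.0, 25.0, seed=12)
    cs = phylo.independent_contrasts(tree, trait)
    assert np.var(cs.values, ddof=1) == pytest.approx(25.0, rel=0.15)
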