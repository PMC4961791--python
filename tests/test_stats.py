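"""Rank tests, binomial test, phylogenetic ANOVA and protein properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from syntevo import (
    DatedTree,
    TraitVector,
    avg_residue_weight,
    binomial_equal_test,
    kruskal_wallis,
    mann_whitney,
    phylo_anova,
    protein_pi,
    simulate_bm_traits,
    simulate_tree,
    steel_dwass,
)
from syntevo.stats import net_charge

from .oracles import brute_force_mwu


class TestMannWhitney:
    def test_small_separated_samples(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0
        assert r.pvalue == pytest.approx(2 / 6)
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.pvalue == pytest.approx(0.1)

    def test_identical_samples_are_central(self):
        r = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(9 / 2)
        assert r.pvalue == pytest.approx(1.0)

    def test_exact_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(1, 8))
            n2 = int(rng.integers(1, 8))
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            u_ref, p_ref = brute_force_mwu(x, y)
            r = mann_whitney(x, y)
            assert r.statistic == pytest.approx(u_ref)
            assert r.pvalue == pytest.approx(p_ref)

    def test_exact_agrees_with_scipy(self, rng):
        for _ in range(20):
            x = rng.choice(500, size=5, replace=False).astype(float)
            y = rng.choice(500, size=6, replace=False).astype(float) + 0.5
            ours = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_used_for_large_or_tied_data(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 14)
        r = mann_whitney(x, y)
        assert "normal" in r.method
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        # 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7
        assert r.statistic == pytest.approx(32 / 7, abs=1e-10)

    def test_two_groups_reduce_to_squared_mwu_z(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(1, 1, 12)
        h = kruskal_wallis([x, y]).statistic
        # tie-corrected z from the normal MWU without continuity correction
        n1, n2 = len(x), len(y)
        u = sum((xi < yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-9)

    def test_agrees_with_scipy_under_ties(self, rng):
        groups = [rng.integers(0, 5, size=8).astype(float) for _ in range(3)]
        ours = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_constant_data(self):
        r = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0


class TestSteelDwass:
    def test_identical_groups_are_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        p = steel_dwass([g, g, g])
        off = p.values[~np.isnan(p.values)]
        assert (off > 0.95).all()

    def test_separated_groups_all_significant(self):
        groups = [
            list(range(1, 6)), list(range(11, 16)), list(range(21, 26))
        ]
        p = steel_dwass(groups)
        off = p.values[~np.isnan(p.values)]
        assert (off < 0.05).all()

    def test_adjusted_p_exceeds_pairwise_p(self, rng):
        groups = [rng.normal(m, 1, 9) for m in (0.0, 0.6, 1.2)]
        adj = steel_dwass(groups)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            raw = mann_whitney(groups[i], groups[j]).pvalue
            assert adj.values[i, j] >= raw - 1e-9

    def test_needs_three_groups_of_two(self):
        with pytest.raises(ValueError):
            steel_dwass([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            steel_dwass([[1, 2], [3, 4], [5]])


class TestBinomialEqualTest:
    def test_exact_tail_sums(self):
        assert binomial_equal_test(3, 13).pvalue == 756 / 8192
        assert binomial_equal_test(0, 20).pvalue == 2 / 2**20
        assert binomial_equal_test(6, 12).pvalue == 1.0

    def test_agrees_with_scipy_minlike(self):
        for k, n in [(2, 10), (7, 15), (13, 40), (0, 5)]:
            ours = binomial_equal_test(k, n).pvalue
            ref = sps.binomtest(k, n, 0.5).pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    @given(st.integers(1, 60), st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetry_about_half(self, n, data):
        k = data.draw(st.integers(0, n))
        assert binomial_equal_test(k, n).pvalue == pytest.approx(
            binomial_equal_test(n - k, n).pvalue
        )


class TestPhyloAnova:
    def test_observed_f_is_classical_anova(self):
        tree = DatedTree.from_newick(
            "((A:10,B:10):10,(C:10,(D:5,(E:2,F:2):3):5):10);"
        )
        traits = TraitVector(
            values=dict(zip("ABCDEF", [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])),
            groups={n: ("g1" if n in "ABC" else "g2") for n in "ABCDEF"},
        )
        r = phylo_anova(tree, traits, n_sim=200, seed=1)
        assert r.statistic == pytest.approx(13.5)

    def test_group_offset_detected_on_star_tree(self):
        star = DatedTree.from_newick(
            "(" + ",".join(f"t{i:02d}:1" for i in range(12)) + ");"
        )
        names = star.leaf_names
        groups = {n: ("a" if i < 6 else "b") for i, n in enumerate(names)}
        tv = simulate_bm_traits(
            star, 1.0, group_effects={"a": 0.0, "b": 4.0}, groups=groups, seed=2
        )
        r = phylo_anova(star, tv, n_sim=500, seed=3)
        assert r.pvalue < 0.01

    def test_degenerate_inputs_rejected(self, quartet_tree):
        flat = TraitVector(
            values={n: 1.0 for n in "ABCD"},
            groups={"A": "g1", "B": "g1", "C": "g2", "D": "g2"},
        )
        with pytest.raises(ValueError):
            phylo_anova(quartet_tree, flat)
        tiny = TraitVector(
            values={"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0},
            groups={"A": "g1", "B": "g2", "C": "g2", "D": "g2"},
        )
        with pytest.raises(ValueError):
            phylo_anova(quartet_tree, tiny)

    def test_null_p_roughly_uniform_on_one_tree(self):
        # compact calibration run; the fuller sweep is in the acceptance suite
        tree = simulate_tree(12, 50.0, 4)
        names = tree.leaf_names
        groups = {n: ("a" if i % 2 else "b") for i, n in enumerate(names)}
        pvals = [
            phylo_anova(
                tree,
                simulate_bm_traits(tree, 1.0, groups=groups, seed=500 + rep),
                n_sim=100,
                seed=rep,
            ).pvalue
            for rep in range(100)
        ]
        assert 0.01 <= np.mean(np.array(pvals) <= 0.05) <= 0.12


class TestProteinProperties:
    def test_single_alanine_pi(self):
        # only the free termini titrate: pI at the midpoint of 3.6 and 8.6
        assert protein_pi("A") == pytest.approx(6.1, abs=1e-4)

    def test_charge_at_pi_is_zero(self, rng):
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            seq = "".join(rng.choice(residues, size=100))
            pi = protein_pi(seq)
            assert abs(net_charge(seq, pi)) < 1e-6

    @pytest.mark.parametrize("res,direction", [("R", +1), ("D", -1)])
    def test_charged_residues_shift_pi(self, res, direction):
        for seq in ["A", "GGG", "ACDEFGHIKLMNPQRSTVWY"]:
            delta = protein_pi(seq + res) - protein_pi(seq)
            assert delta * direction > 0

    def test_average_residue_weight(self):
        assert avg_residue_weight("G") == pytest.approx(57.052, abs=0.01)
        assert avg_residue_weight("GG") == pytest.approx(57.052, abs=0.01)

    def test_weight_is_permutation_invariant(self):
        assert avg_residue_weight("ACDK") == pytest.approx(
            avg_residue_weight("KDCA"), abs=1e-9
        )

    def test_non_standard_residues(self):
        with pytest.raises(ValueError):
            protein_pi("AXZ")
        assert protein_pi("AXZ", skip_unknown=True) == pytest.approx(
            protein_pi("A"), abs=1e-9
        )
        with pytest.raises(ValueError):
            avg_residue_weight("")
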