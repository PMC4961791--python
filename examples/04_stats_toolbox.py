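"""The statistical toolbox on small worked inputs.

Exact Mann-Whitney (enumeration), Kruskal-Wallis with ties, Steel-Dwass
all-pairs comparisons, the exact equal-counts binomial test,
simulation-based phylogenetic ANOVA, and pepstats-style protein
properties.
"""

from syntevo import (
    DatedTree,
    avg_residue_weight,
    binomial_equal_test,
    kruskal_wallis,
    mann_whitney,
    phylo_anova,
    protein_pi,
    simulate_bm_traits,
    steel_dwass,
)

r = mann_whitney([1, 2, 3], [4, 5, 6])
print(f"Mann-Whitney  U={r.statistic:g}  p={r.pvalue:.4f}  ({r.method})")

r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
print(f"Kruskal-Wallis  H={r.statistic:.4f}  p={r.pvalue:.4f}")

p = steel_dwass([[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]])
print("Steel-Dwass adjusted p (well-separated groups):")
print(p.round(4).to_string())

r = binomial_equal_test(3, 13)
print(f"binomial test of equal counts, k=3 n=13: p={r.pvalue:.4f}")

tree = DatedTree.from_newick(
    "((A:10,B:10):10,(C:10,(D:5,(E:2,F:2):3):5):10);"
)
groups = {n: ("low" if n in "ABC" else "high") for n in "ABCDEF"}
traits = simulate_bm_traits(
    tree, sigma2=0.5, group_effects={"low": 0.0, "high": 5.0},
    groups=groups, seed=41,
)
r = phylo_anova(tree, traits, n_sim=1000, seed=41)
print(f"phylogenetic ANOVA  F={r.statistic:.3f}  p={r.pvalue:.4f}")

seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
print(f"pI({seq[:10]}...) = {protein_pi(seq):.3f} pH units")
print(f"average residue weight = {avg_residue_weight(seq):.2f} Da")
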