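"""Block detection, proportion synteny and the exponential-decay rate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntevo import (
    DatedTree,
    GenomeAnnotation,
    OrthologPairSet,
    detect_blocks,
    loss_rate,
    order_genes,
    pairwise_loss_matrix,
    synteny_proportion,
)
from syntevo.synteny import chain_gap_ok, inversion_count

from .conftest import identity_pairs, make_annotation
from .oracles import descending_runs, oracle_blocks


class TestOrderGenes:
    def test_indices_follow_start_coordinates(self):
        df = pd.DataFrame(
            [("g1", "s1", 500, 600, "+"), ("g2", "s1", 100, 200, "+"),
             ("g3", "s1", 300, 400, "-")],
            columns=["gene_id", "scaffold", "start", "end", "strand"],
        )
        out = order_genes(GenomeAnnotation("X", df)).set_index("gene_id")
        assert out.loc["g2", "order"] == 0
        assert out.loc["g3", "order"] == 1
        assert out.loc["g1", "order"] == 2

    def test_scaffolds_indexed_independently(self):
        df = pd.DataFrame(
            [("g1", "s1", 100, 200, "+"), ("g2", "s2", 100, 200, "+"),
             ("g3", "s2", 300, 400, "+")],
            columns=["gene_id", "scaffold", "start", "end", "strand"],
        )
        out = order_genes(GenomeAnnotation("X", df)).set_index("gene_id")
        assert out.loc["g1", "order"] == 0
        assert out.loc["g2", "order"] == 0
        assert out.loc["g3", "order"] == 1

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            [("g1", "s1", 100, 200, "+"), ("g1", "s1", 300, 400, "+")],
            columns=["gene_id", "scaffold", "start", "end", "strand"],
        )
        with pytest.raises(ValueError):
            GenomeAnnotation("X", df)


class TestInversionCount:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (list(range(10)), 0),
            ([0, 1, 2, 3, 6, 5, 4, 7, 8, 9], 1),
            ([9, 8, 7, 6, 5], 1),
            ([1, 0, 3, 2, 5, 4], 3),
            ([0], 0),
            ([], 0),
        ],
    )
    def test_descending_run_counting(self, seq, expected):
        assert inversion_count(seq) == expected

    @given(st.lists(st.integers(0, 50), max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_scan(self, seq):
        assert inversion_count(seq) == descending_runs(seq)


class TestDetectBlocks:
    def test_identical_order_gives_one_clean_block(self):
        genes = [f"g{i}" for i in range(10)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes)
        blocks = detect_blocks(ga, gb, identity_pairs("A", "B", genes))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 10
        assert blocks[0].inversions == 0

    def test_four_collinear_anchors_are_below_the_minimum(self):
        genes = [f"g{i}" for i in range(4)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes)
        assert detect_blocks(ga, gb, identity_pairs("A", "B", genes)) == []

    def test_internal_inversion_counts_once_and_block_survives(self):
        genes = [f"g{i}" for i in range(10)]
        ga = make_annotation("A", genes)
        b_order = genes[:4] + ["g6", "g5", "g4"] + genes[7:]
        gb = make_annotation("B", b_order)
        blocks = detect_blocks(ga, gb, identity_pairs("A", "B", genes))
        assert len(blocks) == 1
        assert blocks[0].inversions == 1
        assert blocks[0].n_anchors == 10

    def test_large_gap_splits_the_chain(self):
        # 12 orthologues, 6 non-orthologous genes inserted in B mid-way
        genes = [f"g{i}" for i in range(12)]
        fillers = [f"f{i}" for i in range(6)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes[:6] + fillers + genes[6:])
        blocks = detect_blocks(ga, gb, identity_pairs("A", "B", genes))
        assert sorted(b.n_anchors for b in blocks) == [6, 6]

    def test_too_many_inversions_disqualify_the_chain(self):
        genes = [f"g{i}" for i in range(12)]
        ga = make_annotation("A", genes)
        # six two-gene flips -> 6 descending runs
        order = []
        for i in range(0, 12, 2):
            order += [genes[i + 1], genes[i]]
        gb = make_annotation("B", order)
        blocks = detect_blocks(ga, gb, identity_pairs("A", "B", genes))
        assert blocks == []

    def test_unknown_gene_in_pairs_rejected(self):
        genes = [f"g{i}" for i in range(6)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes)
        pairs = OrthologPairSet(("A", "B"), {("g0", "nope")})
        with pytest.raises(ValueError):
            detect_blocks(ga, gb, pairs)


def random_instance(rng, max_genes=30, max_anchors=15):
    """Random two-genome instance for oracle comparison."""
    def genome(species, prefix):
        n = int(rng.integers(6, max_genes + 1))
        genes = [f"{prefix}{i}" for i in range(n)]
        perm = rng.permutation(n)
        n_scaf = int(rng.integers(1, 3))
        cut = int(rng.integers(1, n)) if n_scaf == 2 else n
        rows = []
        for pos, k in enumerate(perm):
            scaf = "s1" if pos < cut else "s2"
            i = pos if pos < cut else pos - cut
            rows.append(
                (genes[k], scaf, 1 + i * 10, 5 + i * 10,
                 "+" if rng.random() < 0.5 else "-")
            )
        df = pd.DataFrame(
            rows, columns=["gene_id", "scaffold", "start", "end", "strand"]
        )
        return GenomeAnnotation(species, df), genes

    ga, genes_a = genome("A", "a")
    gb, genes_b = genome("B", "b")
    k = int(rng.integers(0, min(len(genes_a), len(genes_b), max_anchors) + 1))
    sel_a = rng.choice(len(genes_a), size=k, replace=False)
    sel_b = rng.choice(len(genes_b), size=k, replace=False)
    links = {(genes_a[i], genes_b[j]) for i, j in zip(sel_a, sel_b)}
    return ga, gb, OrthologPairSet(("A", "B"), links)


class TestOracleAgreement:
    def test_matches_exhaustive_chain_enumeration(self, rng):
        # full 500-instance sweep lives in the acceptance suite
        for _ in range(100):
            ga, gb, pairs = random_instance(rng)
            got = {
                tuple(an.gene_a for an in b.anchors)
                for b in detect_blocks(ga, gb, pairs, min_genes=3)
            }
            want = oracle_blocks(ga, gb, pairs, min_genes=3)
            assert got == want


class TestSyntenyProportion:
    def test_ratio_of_anchors_in_blocks(self):
        genes = [f"g{i}" for i in range(8)]
        extra = {("x1", "y1"), ("x2", "y2")}
        ga = make_annotation("A", genes + ["x1", "x2"])
        gb = make_annotation("B", genes[::-1] + ["y2", "y1"])
        # reversal keeps one block of 8; x/y anchors are dispersed
        pairs = OrthologPairSet(
            ("A", "B"), {(g, g) for g in genes} | extra
        )
        blocks = detect_blocks(ga, gb, pairs, min_genes=5)
        assert synteny_proportion(blocks, pairs) == pytest.approx(0.8)

    def test_identity_genomes_give_full_synteny(self):
        genes = [f"g{i}" for i in range(20)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes)
        pairs = identity_pairs("A", "B", genes)
        assert synteny_proportion(detect_blocks(ga, gb, pairs), pairs) == 1.0

    def test_no_blocks_gives_zero(self):
        genes = [f"g{i}" for i in range(3)]
        ga = make_annotation("A", genes)
        gb = make_annotation("B", genes)
        pairs = identity_pairs("A", "B", genes)
        assert synteny_proportion([], pairs) == 0.0

    def test_empty_pairs_is_degenerate(self):
        with pytest.raises(ValueError):
            synteny_proportion([], OrthologPairSet(("A", "B"), set()))


class TestLossRate:
    def test_no_loss_and_perfect_square(self):
        assert loss_rate(1.0, 37.0) == 0.0
        assert loss_rate(0.81, 2.0) == pytest.approx(0.1, abs=1e-15)

    def test_half_synteny_at_deep_divergence(self):
        assert loss_rate(0.5, 100.0) == pytest.approx(0.0069075045629, abs=1e-12)

    def test_total_loss_saturates_with_warning(self):
        with pytest.warns(UserWarning):
            assert loss_rate(0.0, 10.0) == 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            loss_rate(1.2, 10.0)
        with pytest.raises(ValueError):
            loss_rate(0.5, 0.0)

    @given(
        st.floats(0.05, 1.0), st.floats(0.05, 1.0), st.floats(1.0, 200.0)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing_in_ps(self, p1, p2, T):
        lo, hi = sorted((p1, p2))
        assert loss_rate(lo, T) >= loss_rate(hi, T)


class TestPairwiseLossMatrix:
    def test_identical_genomes_give_zero_matrices(self, quartet_tree):
        genes = [f"g{i}" for i in range(12)]
        genomes = {sp: make_annotation(sp, genes) for sp in "ABCD"}
        pairsets = {
            frozenset([a, b]): identity_pairs(a, b, genes)
            for a in "ABCD" for b in "ABCD" if a < b
        }
        loss, rate = pairwise_loss_matrix(genomes, pairsets, quartet_tree)
        assert np.allclose(loss.values, 0)
        assert np.allclose(rate.values, 0)

    def test_two_species_composition(self):
        tree = DatedTree.from_newick("(A:2,B:2);")
        genes = [f"g{i}" for i in range(8)]
        extra = {("x1", "y1"), ("x2", "y2")}
        genomes = {
            "A": make_annotation("A", genes + ["x1", "x2"]),
            "B": make_annotation("B", genes[::-1] + ["y2", "y1"]),
        }
        pairs = OrthologPairSet(("A", "B"), {(g, g) for g in genes} | extra)
        loss, rate = pairwise_loss_matrix(
            genomes, {frozenset("AB"): pairs}, tree
        )
        assert loss.loc("A", "B") == pytest.approx(0.2)
        # p_s = 0.8, T = 2 -> 1 - 0.8^(1/2)
        assert rate.loc("A", "B") == pytest.approx(1 - 0.8**0.5)

    def test_species_missing_from_tree_rejected(self, quartet_tree):
        genes = ["g0"]
        genomes = {"A": make_annotation("A", genes), "Z": make_annotation("Z", genes)}
        with pytest.raises(ValueError):
            pairwise_loss_matrix(
                genomes, {frozenset("AZ"): identity_pairs("A", "Z", genes)},
                quartet_tree,
            )


def test_chain_gap_rule_is_symmetric_in_direction_of_b():
    from syntevo.synteny import Anchor

    a1 = Anchor("a", "b", "s", 0, "s", 10, True)
    a2 = Anchor("c", "d", "s", 3, "s", 5, True)
    assert chain_gap_ok(a1, a2, max_gap=4)
    assert not chain_gap_ok(a1, a2, max_gap=3)
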