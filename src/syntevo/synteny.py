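"""Syntenic-block detection and synteny-loss rates for species pairs.

Synteny here means conservation of gene order between two genomes.  The
unit of comparison is the *anchor*: a one-to-one orthologous gene pair
placed at its gene-order index on a scaffold of each genome.  Anchors on
a shared scaffold pair are chained left-to-right into blocks under the
classic rules: a block holds at least ``min_genes`` anchors, may be
extended across gaps of at most ``max_gap`` intervening genes (enforced
in the gene-index space of *both* genomes), and may contain at most
``max_inversions`` gene inversions, counted as maximal strictly
descending runs (length >= 2) of the partner-genome index sequence.

The proportion-synteny statistic p_s is the fraction of anchors that
fall inside valid blocks.  Under an exponential-decay model of synteny
loss over a divergence time of T MY, the per-MY loss rate is

    rate = 1 - p_s^(1/T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .orthology import OrthologPairSet
from .treefit import DistanceMatrix
from .trees import DatedTree

__all__ = [
    "GenomeAnnotation",
    "Anchor",
    "SyntenyBlock",
    "SyntenyStats",
    "order_genes",
    "detect_blocks",
    "synteny_proportion",
    "loss_rate",
    "pair_synteny_stats",
    "pairwise_loss_matrix",
]

COLUMNS = ["gene_id", "scaffold", "start", "end", "strand"]


@dataclass
class GenomeAnnotation:
    """Ordered gene placements (scaffold, coordinates, strand) for one species.

    ``df`` holds one row per gene with columns gene_id, scaffold, start,
    end (1-based inclusive bp) and strand ('+'/'-').  Gene order on each
    scaffold is derived from start coordinates.
    """

    species: str
    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id: {dup}")
        if (df["start"] > df["end"]).any():
            raise ValueError("start must be <= end")
        if df.duplicated(["scaffold", "start"]).any():
            raise ValueError("two genes share a start coordinate on one scaffold")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.df = df[COLUMNS]

    @property
    def n_genes(self) -> int:
        return len(self.df)


class Anchor(NamedTuple):
    gene_a: str
    gene_b: str
    scaffold_a: str
    idx_a: int
    scaffold_b: str
    idx_b: int
    same_orientation: bool


@dataclass
class SyntenyBlock:
    species: tuple[str, str]
    scaffold_a: str
    scaffold_b: str
    anchors: list[Anchor]
    inversions: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyStats:
    species: tuple[str, str]
    n_anchors: int
    n_in_blocks: int
    p_s: float
    divergence_time: float
    rate: float
    blocks: list[SyntenyBlock] = field(repr=False, default_factory=list)


def order_genes(g: GenomeAnnotation) -> pd.DataFrame:
    """Annotation with a 0-based per-scaffold gene-order index.

    Genes are ranked by start coordinate within each scaffold (gene id
    breaks ties, though equal starts are rejected upstream).
    """
    df = g.df.sort_values(["scaffold", "start", "gene_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["order"] = df.groupby("scaffold", sort=False).cumcount()
    return df


def _anchors(ga: GenomeAnnotation, gb: GenomeAnnotation, pairs: OrthologPairSet):
    oa = order_genes(ga).set_index("gene_id")
    ob = order_genes(gb).set_index("gene_id")
    links = pairs.oriented(ga.species, gb.species)
    anchors = []
    for a_gene, b_gene in links:
        if a_gene not in oa.index:
            raise ValueError(f"gene {a_gene!r} not in {ga.species} annotation")
        if b_gene not in ob.index:
            raise ValueError(f"gene {b_gene!r} not in {gb.species} annotation")
        ra, rb = oa.loc[a_gene], ob.loc[b_gene]
        anchors.append(
            Anchor(
                a_gene,
                b_gene,
                ra["scaffold"],
                int(ra["order"]),
                rb["scaffold"],
                int(rb["order"]),
                ra["strand"] == rb["strand"],
            )
        )
    return anchors


def inversion_count(idx_b: list[int]) -> int:
    """Number of maximal strictly descending runs (length >= 2)."""
    runs = 0
    k = 0
    for i in range(1, len(idx_b)):
        if idx_b[i] < idx_b[i - 1]:
            k += 1
        else:
            if k >= 1:
                runs += 1
            k = 0
    if k >= 1:
        runs += 1
    return runs


def chain_gap_ok(prev: Anchor, nxt: Anchor, max_gap: int) -> bool:
    """Gap rule between consecutive anchors, enforced in both genomes."""
    gap_a = nxt.idx_a - prev.idx_a - 1
    gap_b = abs(nxt.idx_b - prev.idx_b) - 1
    return gap_a <= max_gap and gap_b <= max_gap


def detect_blocks(
    ga: GenomeAnnotation,
    gb: GenomeAnnotation,
    pairs: OrthologPairSet,
    min_genes: int = 5,
    max_gap: int = 4,
    max_inversions: int = 5,
) -> list[SyntenyBlock]:
    """Chain orthologue anchors into syntenic blocks.

    Anchors are grouped by scaffold pair, sorted by index in genome A,
    and chained greedily left to right: an anchor joins the open chain
    iff the gap to the previous anchor is within ``max_gap`` in both
    genomes; otherwise the chain closes and a new one starts.  Chains
    with at least ``min_genes`` anchors and at most ``max_inversions``
    inversions become blocks; every anchor belongs to at most one block.
    """
    anchors = _anchors(ga, gb, pairs)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for an in anchors:
        groups.setdefault((an.scaffold_a, an.scaffold_b), []).append(an)

    blocks = []
    for (sca, scb), group in sorted(groups.items()):
        group.sort(key=lambda an: an.idx_a)
        chain: list[Anchor] = []
        for an in group:
            if chain and not chain_gap_ok(chain[-1], an, max_gap):
                blocks.extend(
                    _close_chain(ga, gb, sca, scb, chain, min_genes, max_inversions)
                )
                chain = []
            chain.append(an)
        blocks.extend(
            _close_chain(ga, gb, sca, scb, chain, min_genes, max_inversions)
        )
    return blocks


def _close_chain(ga, gb, sca, scb, chain, min_genes, max_inversions):
    if len(chain) < min_genes:
        return []
    inv = inversion_count([an.idx_b for an in chain])
    if inv > max_inversions:
        return []
    return [SyntenyBlock((ga.species, gb.species), sca, scb, list(chain), inv)]


def synteny_proportion(blocks: list[SyntenyBlock], pairs: OrthologPairSet) -> float:
    """p_s = anchors inside valid blocks / total one-to-one anchors."""
    total = len(pairs.links)
    if total == 0:
        raise ValueError("no orthologue anchors: proportion synteny undefined")
    inside = sum(b.n_anchors for b in blocks)
    return inside / total


def loss_rate(p_s: float, T: float) -> float:
    """Per-MY synteny-loss rate 1 - p_s^(1/T) under exponential decay."""
    if not 0.0 <= p_s <= 1.0:
        raise ValueError("p_s must lie in [0, 1]")
    if T <= 0:
        raise ValueError("divergence time must be positive")
    if p_s == 0.0:
        warnings.warn("p_s = 0: synteny completely lost, rate saturates at 1")
        return 1.0
    return 1.0 - p_s ** (1.0 / T)


def pair_synteny_stats(
    ga: GenomeAnnotation,
    gb: GenomeAnnotation,
    pairs: OrthologPairSet,
    divergence_time: float,
    min_genes: int = 5,
    max_gap: int = 4,
    max_inversions: int = 5,
) -> SyntenyStats:
    """Blocks, p_s and loss rate for one species pair."""
    blocks = detect_blocks(ga, gb, pairs, min_genes, max_gap, max_inversions)
    p_s = synteny_proportion(blocks, pairs)
    return SyntenyStats(
        species=(ga.species, gb.species),
        n_anchors=len(pairs.links),
        n_in_blocks=sum(b.n_anchors for b in blocks),
        p_s=p_s,
        divergence_time=divergence_time,
        rate=loss_rate(p_s, divergence_time),
        blocks=blocks,
    )


def pairwise_loss_matrix(
    genomes: dict[str, GenomeAnnotation],
    pairsets: dict[frozenset, OrthologPairSet],
    dated_tree: DatedTree,
    min_genes: int = 5,
    max_gap: int = 4,
    max_inversions: int = 5,
    double_time: bool = False,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Synteny-loss (1 - p_s) and per-MY-rate matrices over all pairs.

    Divergence time T for a pair is the age of their MRCA in the dated
    tree (set ``double_time`` to use the 2T total path length instead).
    """
    names = sorted(genomes)
    missing = set(names) - set(dated_tree.leaf_names)
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    n = len(names)
    loss = np.zeros((n, n))
    rates = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = names[i], names[j]
            pairs = pairsets[frozenset([a, b])]
            T = dated_tree.mrca_age(a, b)
            if double_time:
                T *= 2.0
            st = pair_synteny_stats(
                genomes[a], genomes[b], pairs, T, min_genes, max_gap, max_inversions
            )
            loss[i, j] = loss[j, i] = 1.0 - st.p_s
            rates[i, j] = rates[j, i] = st.rate
    return DistanceMatrix(names, loss), DistanceMatrix(names, rates)
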