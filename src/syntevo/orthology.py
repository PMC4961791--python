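"""Reciprocal-best-hit orthology from pairwise similarity tables.

One-to-one orthologue pairs between two genomes are called as reciprocal
best hits (RBH): gene *a* and gene *b* are orthologues iff *b* is the
top-scoring hit of *a* and *a* is the top-scoring hit of *b*, among hits
passing an e-value cutoff (1e-5 by default).  "Best" is decided by bit
score, with ties broken by e-value and then subject id, so results are
deterministic.  Multi-species one-per-species groups are assembled as
connected components of the pairwise-link graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "OUTFMT6_COLUMNS",
    "HitTable",
    "OrthologPairSet",
    "OrthoGroup",
    "rbh_pairs",
    "build_one2one_groups",
]

logger = logging.getLogger(__name__)

# BLAST tabular (outfmt 6) column order
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitTable:
    """Similarity hits from one query species against one subject species."""

    query_species: str
    subject_species: str
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in OUTFMT6_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"hit table missing columns: {missing}")
        df = self.df[OUTFMT6_COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["evalue"] < 0).any():
                raise ValueError("e-values must be >= 0")
            if (df["bitscore"] <= 0).any() or not df["bitscore"].map(
                lambda x: x == x and abs(x) != float("inf")
            ).all():
                raise ValueError("bit scores must be finite and positive")
            if (df["qseqid"].astype(str) == "").any() or (
                df["sseqid"].astype(str) == ""
            ).any():
                raise ValueError("gene ids must be non-empty")
        self.df = df


@dataclass
class OrthologPairSet:
    """One-to-one orthologue links for an unordered species pair.

    ``links`` holds (gene in species_a, gene in species_b) with
    ``species = (species_a, species_b)`` stored in sorted order.
    """

    species: tuple[str, str]
    links: set = field(default_factory=set)

    def __post_init__(self):
        a, b = self.species
        if not a < b:
            self.species = (b, a)
            self.links = {(gb, ga) for ga, gb in self.links}
        seen_a, seen_b = set(), set()
        for ga, gb in self.links:
            if ga in seen_a or gb in seen_b:
                raise ValueError("pair set is not one-to-one")
            seen_a.add(ga)
            seen_b.add(gb)

    def oriented(self, first: str, second: str) -> set:
        """Links as (gene of `first`, gene of `second`)."""
        if (first, second) == self.species:
            return set(self.links)
        if (second, first) == self.species:
            return {(gb, ga) for ga, gb in self.links}
        raise ValueError(
            f"pair set is for {self.species}, not {(first, second)}"
        )

    def __len__(self) -> int:
        return len(self.links)


@dataclass
class OrthoGroup:
    """One gene per species, for two or more species."""

    members: dict  # species -> gene id

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an orthologue group needs >= 2 species")


def _best_hits(df: pd.DataFrame, evalue_max: float) -> dict:
    """Best subject per query: max bit score, ties -> min e-value -> id."""
    kept = df[df["evalue"] < evalue_max]
    if kept.empty:
        return {}
    ranked = kept.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


def rbh_pairs(
    hits_ab: HitTable, hits_ba: HitTable, evalue_max: float = 1e-5
) -> OrthologPairSet:
    """Reciprocal best hits between two species.

    ``hits_ab`` and ``hits_ba`` must be the two directions of the same
    species pair.  A link (a, b) is emitted iff b is a's best hit and a
    is b's best hit after the e-value filter; the result is one-to-one
    by construction.
    """
    if (hits_ab.query_species, hits_ab.subject_species) != (
        hits_ba.subject_species,
        hits_ba.query_species,
    ):
        raise ValueError(
            "hit tables are not reciprocal directions of one species pair"
        )
    best_ab = _best_hits(hits_ab.df, evalue_max)
    best_ba = _best_hits(hits_ba.df, evalue_max)
    links = {
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    }
    return OrthologPairSet(
        species=(hits_ab.query_species, hits_ab.subject_species), links=links
    )


def build_one2one_groups(
    pairsets: list[OrthologPairSet],
    species: list[str],
    require_all: bool = True,
) -> list[OrthoGroup]:
    """Combine pairwise links into multi-species one-to-one groups.

    Genes are nodes of a graph with one edge per pairwise link;
    connected components with at most one gene per species become
    groups.  Components carrying two or more genes from any species are
    discarded (and logged).  With ``require_all`` only components
    containing exactly one gene from *every* species are kept.
    """
    species_set = set(species)
    for ps in pairsets:
        if not set(ps.species) <= species_set:
            raise ValueError(f"pair set {ps.species} outside species list")
    graph = nx.Graph()
    for ps in pairsets:
        sa, sb = ps.species
        for ga, gb in ps.links:
            graph.add_edge((sa, ga), (sb, gb))
    groups = []
    n_conflict = 0
    for comp in nx.connected_components(graph):
        members: dict[str, str] = {}
        ok = True
        for sp, gene in comp:
            if sp in members:
                ok = False
                break
            members[sp] = gene
        if not ok:
            n_conflict += 1
            continue
        if require_all and set(members) != species_set:
            continue
        groups.append(OrthoGroup(members=members))
    if n_conflict:
        logger.info("discarded %d components with within-species conflicts", n_conflict)
    groups.sort(key=lambda g: sorted(g.members.items()))
    return groups
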