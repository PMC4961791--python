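"""Synthetic genomes, hit tables, family counts and traits on dated trees.

This generator produces data with the statistical structure the rest of
the package assumes, so every analysis stage can be exercised and
calibrated without external genome data:

* gene orders diverging along a dated tree by inversions, translocations,
  gene losses and gene gains, with per-branch event counts Poisson in
  (rate x branch duration) — the continuous-time process whose pairwise
  signature is exponential decay of synteny;
* BLAST-like tabular hit tables in which every surviving orthologue pair
  is a top reciprocal hit and paralog noise scores strictly lower;
* gene-family size matrices evolving by a gain/loss step process, with
  optional clade-specific expansion shifts;
* Brownian-motion trait values with optional additive group effects.

Randomness is organised as named substreams: one per branch (derived
from the master seed and a hash of the clade below the branch) for event
counts, and one per individual event, keyed by (branch, event type,
event index).  Event counts are drawn by inverting the Poisson CDF on a
branch-level uniform, so for a fixed seed, raising one event rate only
*adds* events of that type while every other event — and the shared
prefix of same-type events — stays identical.  This monotone coupling
makes dose-response comparisons across rates well behaved and keeps
per-branch results stable when unrelated settings change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import poisson

from .famdyn import FamilyCounts
from .orthology import OUTFMT6_COLUMNS, HitTable
from .stats import TraitVector
from .synteny import GenomeAnnotation
from .trees import DatedTree, branch_key

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_tree",
    "simulate_genomes",
    "simulate_hit_tables",
    "simulate_family_counts",
    "simulate_bm_traits",
]

GENE_LENGTH = 1000  # bp per emitted gene
GENE_SPACER = 100  # bp between genes


@dataclass
class SimConfig:
    """Parameters of the genome-rearrangement simulation.

    Rates are per million years; ``gene_loss_rate`` is per gene per MY.
    ``inversion_span_mean`` is the mean of the truncated-geometric
    segment length (in genes) used for inversions and translocations.
    The default of 10 genes per scaffold mirrors the fragmentation of
    short-read draft assemblies, where most gene-bearing scaffolds hold
    only a handful of genes.
    """

    n_scaffolds: int = 200
    n_genes: int = 2000
    inversion_rate: float = 0.1
    translocation_rate: float = 0.02
    gene_loss_rate: float = 0.001
    gene_gain_rate: float = 0.5
    inversion_span_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_scaffolds < 1 or self.n_genes < 1:
            raise ValueError("n_scaffolds and n_genes must be positive")
        if self.n_genes < self.n_scaffolds:
            raise ValueError("need at least one gene per scaffold")
        for name in (
            "inversion_rate",
            "translocation_rate",
            "gene_loss_rate",
            "gene_gain_rate",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.inversion_span_mean < 1:
            raise ValueError("inversion_span_mean must be >= 1")


@dataclass
class TruthSet:
    """True orthology and event history of a simulation run.

    ``ortholog_map`` maps each ancestral gene id to, per species, its
    surviving descendant id (simulated genes keep their id) or None.
    ``event_log`` records (branch clade label, event type, segment size).
    """

    ortholog_map: dict
    event_log: list = field(default_factory=list)

    def surviving_pairs(self, sp_a: str, sp_b: str) -> set:
        out = set()
        for anc, per_sp in self.ortholog_map.items():
            ga, gb = per_sp.get(sp_a), per_sp.get(sp_b)
            if ga is not None and gb is not None:
                out.add((ga, gb))
        return out


# ---------------------------------------------------------------------------
# trees


def simulate_tree(n_taxa: int, crown_age: float, seed: int) -> DatedTree:
    """Random rooted binary ultrametric tree with root age ``crown_age``.

    Topology is built by merging random lineage pairs at n_taxa - 1
    node ages drawn uniformly below the crown age (the last merge is
    pinned at the crown age exactly).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if crown_age <= 0:
        raise ValueError("crown age must be positive")
    rng = np.random.default_rng(seed)
    names = [f"t{i + 1:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(names)
    lineages = []
    for name in names:
        node = dendropy.Node(taxon=ns.get_taxon(name))
        node.age = 0.0
        lineages.append(node)
    inner = sorted(rng.uniform(0.0, crown_age, size=max(0, n_taxa - 2)))
    for age in list(inner) + [crown_age]:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        parent = dendropy.Node()
        parent.age = float(age)
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = parent.age - child.age
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=lineages[0])
    return DatedTree(tree)


def _branch_rng(master_seed: int, clade, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), stream, branch_key(clade)])
    )


# ---------------------------------------------------------------------------
# genomes

# internal genome representation: list of scaffolds, each a list of
# (gene_id, strand) with strand +1/-1


def _ancestral_genome(cfg: SimConfig):
    ids = [f"g{i + 1:06d}" for i in range(cfg.n_genes)]
    bounds = np.linspace(0, cfg.n_genes, cfg.n_scaffolds + 1).astype(int)
    return [
        [(g, 1) for g in ids[bounds[s] : bounds[s + 1]]]
        for s in range(cfg.n_scaffolds)
    ]


_EVENT_TYPES = ("inversion", "translocation", "loss", "gain")


def _geometric_from_uniform(u: float, mean: float, limit: int) -> int:
    """Inverse-CDF geometric draw (support 1, 2, ...), truncated."""
    p = 1.0 / mean
    if p >= 1.0:
        return 1
    span = 1 + int(np.floor(np.log1p(-u) / np.log1p(-p)))
    return max(1, min(span, limit))


def _weighted_pick(u: float, weights) -> int:
    c = np.cumsum(np.asarray(weights, dtype=float))
    if c[-1] <= 0:
        return -1
    return int(np.searchsorted(c, u * c[-1], side="right"))


def _poisson_count(u: float, lam: float) -> int:
    if lam <= 0:
        return 0
    return max(0, int(poisson.ppf(max(u, 1e-300), lam)))


def _event_rng(seed: int, clade_key: int, type_code: int, i: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), 0, clade_key, type_code, i])
    )


def _evolve_branch(
    genome, duration, cfg: SimConfig, seed: int, clade_key: int, tag: str,
    log: list,
):
    genome = [list(sc) for sc in genome]
    n_now = sum(len(sc) for sc in genome)
    lam = {
        "inversion": cfg.inversion_rate * duration,
        "translocation": cfg.translocation_rate * duration,
        "loss": cfg.gene_loss_rate * duration * n_now,
        "gain": cfg.gene_gain_rate * duration,
    }
    crng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0, clade_key, 100])
    )
    u_counts = crng.random(len(_EVENT_TYPES))
    counts = {
        t: _poisson_count(u, lam[t]) for t, u in zip(_EVENT_TYPES, u_counts)
    }
    events = [
        (t, i) for t in _EVENT_TYPES for i in range(counts[t])
    ]
    orng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0, clade_key, 101])
    )
    orng.shuffle(events)
    for ev, i in events:
        rng = _event_rng(seed, clade_key, _EVENT_TYPES.index(ev), i)
        if ev == "inversion":
            s = _weighted_pick(rng.random(), [len(sc) for sc in genome])
            if s < 0:
                continue
            span = _geometric_from_uniform(
                rng.random(), cfg.inversion_span_mean, len(genome[s])
            )
            lo = int(rng.random() * (len(genome[s]) - span + 1))
            seg = genome[s][lo : lo + span]
            genome[s][lo : lo + span] = [(g, -st) for g, st in reversed(seg)]
            log.append((tag, "inversion", span))
        elif ev == "translocation":
            s = _weighted_pick(rng.random(), [len(sc) for sc in genome])
            if s < 0:
                continue
            span = _geometric_from_uniform(
                rng.random(), cfg.inversion_span_mean, len(genome[s])
            )
            lo = int(rng.random() * (len(genome[s]) - span + 1))
            seg = genome[s][lo : lo + span]
            del genome[s][lo : lo + span]
            t = _weighted_pick(rng.random(), [len(sc) + 1 for sc in genome])
            pos = int(rng.random() * (len(genome[t]) + 1))
            genome[t][pos:pos] = seg
            log.append((tag, "translocation", span))
        elif ev == "loss":
            total = sum(len(sc) for sc in genome)
            if total == 0:
                continue
            k = int(rng.random() * total)
            for sc in genome:
                if k < len(sc):
                    del sc[k]
                    break
                k -= len(sc)
            log.append((tag, "loss", 1))
        else:  # gain
            gid = f"x{clade_key & 0xFFFFFF:06x}_{i + 1:04d}"
            t = _weighted_pick(rng.random(), [len(sc) + 1 for sc in genome])
            pos = int(rng.random() * (len(genome[t]) + 1))
            strand = 1 if rng.random() < 0.5 else -1
            genome[t].insert(pos, (gid, strand))
            log.append((tag, "gain", 1))
    return genome


def _emit_annotation(species: str, genome) -> GenomeAnnotation:
    rows = []
    for s, scaffold in enumerate(genome):
        for i, (gid, strand) in enumerate(scaffold):
            start = 1 + i * (GENE_LENGTH + GENE_SPACER)
            rows.append(
                (gid, f"scf{s + 1:03d}", start, start + GENE_LENGTH - 1,
                 "+" if strand > 0 else "-")
            )
    df = pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "start", "end", "strand"]
    )
    return GenomeAnnotation(species=species, df=df)


def simulate_genomes(
    tree: DatedTree, cfg: SimConfig
) -> tuple[dict[str, GenomeAnnotation], TruthSet]:
    """Evolve an ancestral gene order along every branch of ``tree``.

    Returns per-species annotations (non-overlapping 1-based intervals,
    in gene order) and the :class:`TruthSet` with the true orthology and
    the event log.
    """
    log: list = []
    out: dict[str, GenomeAnnotation] = {}

    def recurse(node, genome):
        for child in node.child_nodes():
            clade = tree.clade(child)
            tag = ",".join(sorted(clade))
            child_genome = _evolve_branch(
                genome, node.age - child.age, cfg, cfg.seed,
                branch_key(clade), tag, log,
            )
            if child.is_leaf():
                out[child.taxon.label] = _emit_annotation(
                    child.taxon.label, child_genome
                )
            else:
                recurse(child, child_genome)

    ancestral = _ancestral_genome(cfg)
    recurse(tree.root, ancestral)

    anc_ids = [g for sc in ancestral for g, _ in sc]
    present = {
        sp: set(ann.df["gene_id"]) for sp, ann in out.items()
    }
    ortholog_map = {
        gid: {sp: (gid if gid in present[sp] else None) for sp in out}
        for gid in anc_ids
    }
    return out, TruthSet(ortholog_map=ortholog_map, event_log=log)


# ---------------------------------------------------------------------------
# hit tables

_TRUE_SCORE = (200.0, 400.0)  # true-orthologue bit-score range
_NOISE_SCORE = (50.0, 150.0)  # spurious hits score strictly below the margin


def _hit_row(q, s, score, pident, rng):
    length = 300
    return (
        q, s, round(pident, 2), length, int(length * (100 - pident) / 100), 0,
        1, length, 1, length, 10.0 ** (-score / 10.0), round(score, 2),
    )


def simulate_hit_tables(
    genomes: dict[str, GenomeAnnotation],
    truth: TruthSet,
    noise: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, str], HitTable]:
    """BLAST-like hit tables for every ordered species pair.

    Every surviving orthologue pair gets a top hit in both directions
    with a bit score above a fixed margin; with probability ``noise``
    per gene, a spurious hit to a random partner gene is added with a
    strictly lower score.  E-values decrease monotonically with score.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must lie in [0, 1]")
    species = sorted(genomes)
    tables: dict[tuple[str, str], HitTable] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(seed), 3, branch_key([a]), branch_key([b])]
                )
            )
            rows_ab, rows_ba = [], []
            for ga, gb in sorted(truth.surviving_pairs(a, b)):
                score = rng.uniform(*_TRUE_SCORE)
                pident = rng.uniform(85, 100)
                rows_ab.append(_hit_row(ga, gb, score, pident, rng))
                rows_ba.append(_hit_row(gb, ga, score, pident, rng))
            if noise > 0:
                genes_a = sorted(genomes[a].df["gene_id"])
                genes_b = sorted(genomes[b].df["gene_id"])
                for src, pool, rows in (
                    (genes_a, genes_b, rows_ab),
                    (genes_b, genes_a, rows_ba),
                ):
                    for g in src:
                        if rng.random() < noise:
                            tgt = pool[int(rng.integers(0, len(pool)))]
                            score = rng.uniform(*_NOISE_SCORE)
                            rows.append(
                                _hit_row(g, tgt, score, rng.uniform(30, 60), rng)
                            )
            tables[(a, b)] = HitTable(
                a, b, pd.DataFrame(rows_ab, columns=OUTFMT6_COLUMNS)
            )
            tables[(b, a)] = HitTable(
                b, a, pd.DataFrame(rows_ba, columns=OUTFMT6_COLUMNS)
            )
    return tables


# ---------------------------------------------------------------------------
# gene families

def simulate_family_counts(
    tree: DatedTree,
    n_families: int,
    base_lambda: float,
    shift: tuple | None = None,
    seed: int = 0,
    root_mean: float = 10.0,
) -> FamilyCounts:
    """Family sizes evolving by a gain/loss step process along the tree.

    Per branch of duration t each family gains Poisson(lambda_g * t) and
    loses Poisson(base_lambda * t) members (floored at 0).  Without a
    shift, lambda_g = base_lambda and sizes drift without trend.
    ``shift = (clade_leaves, multiplier)`` multiplies the gain intensity
    on every branch inside the clade, producing directional expansion
    (multiplier > 1) or contraction (< 1) of in-clade families.
    """
    rng0 = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    root_sizes = rng0.poisson(root_mean, size=n_families).astype(np.int64)
    shift_clade = None
    mult = 1.0
    if shift is not None:
        clade_leaves, mult = shift
        shift_clade = tree.clade(tree.node_for_clade(clade_leaves))
        node = tree.node_for_clade(clade_leaves)
        if node.is_leaf():
            raise ValueError("shift node must be internal")
    cols: dict[str, np.ndarray] = {}

    def recurse(node, sizes):
        for child in node.child_nodes():
            clade = tree.clade(child)
            t = node.age - child.age
            rng = _branch_rng(seed, clade, stream=1)
            lam_gain = base_lambda
            if shift_clade is not None and clade <= shift_clade:
                lam_gain = base_lambda * mult
            gains = rng.poisson(lam_gain * t, size=n_families)
            losses = rng.poisson(base_lambda * t, size=n_families)
            child_sizes = np.maximum(0, sizes + gains - losses)
            if child.is_leaf():
                cols[child.taxon.label] = child_sizes
            else:
                recurse(child, child_sizes)

    recurse(tree.root, root_sizes)
    index = [f"fam{i + 1:05d}" for i in range(n_families)]
    df = pd.DataFrame(cols, index=index)[sorted(cols)]
    return FamilyCounts(df=df)


# ---------------------------------------------------------------------------
# traits

def simulate_bm_traits(
    tree: DatedTree,
    sigma2: float,
    group_effects: dict | None = None,
    groups: dict | None = None,
    seed: int = 0,
) -> TraitVector:
    """Brownian-motion trait values at the leaves, plus group offsets.

    The trait starts at 0 at the root and accumulates independent
    Normal(0, sigma2 * t) increments along each branch; each leaf then
    receives the additive offset of its group (default: one group,
    offset 0).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    groups = groups or {name: "all" for name in tree.leaf_names}
    group_effects = group_effects or {}
    values: dict[str, float] = {}

    def recurse(node, x):
        for child in node.child_nodes():
            clade = tree.clade(child)
            t = node.age - child.age
            rng = _branch_rng(seed, clade, stream=2)
            y = x + rng.normal(0.0, np.sqrt(sigma2 * t)) if t > 0 else x
            if child.is_leaf():
                name = child.taxon.label
                values[name] = y + group_effects.get(groups[name], 0.0)
            else:
                recurse(child, y)

    recurse(tree.root, 0.0)
    return TraitVector(values=values, groups=dict(groups))
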