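"""End-to-end analysis pipeline.

Runs (or ingests) a simulation, calls orthologues, measures pairwise
synteny and loss rates, fits branch losses onto the dated tree, scores
gene-family dynamics, and aggregates everything into a run directory of
TSV/PHYLIP/newick artifacts plus a machine-readable ``report.json``.
Every output file carries a metadata header with the package version,
a hash of the configuration and the master seed, so runs are auditable
and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .famdyn import permutation_percentiles
from .io import (
    write_annotation,
    write_blocks,
    write_distance_matrix,
    write_family_counts,
    write_hit_table,
    write_pairset,
    write_truth,
)
from .orthology import rbh_pairs
from .simulate import (
    SimConfig,
    simulate_family_counts,
    simulate_genomes,
    simulate_hit_tables,
    simulate_tree,
)
from .synteny import pair_synteny_stats, pairwise_loss_matrix
from .treefit import branch_rates, fit_branch_lengths

logger = logging.getLogger(__name__)

# Analysis defaults.  A syntenic block holds at least five contiguous
# orthologous genes; blocks extend across gaps of no more than 4 genes;
# no more than 5 gene inversions are allowed per block; reciprocal best
# hits require e-value < 1e-5; distance fitting weights pairs by
# d^(-2) (Fitch-Margoliash).
MIN_BLOCK_GENES = 5
MAX_BLOCK_GAP = 4
MAX_BLOCK_INVERSIONS = 5
RBH_EVALUE_MAX = 1e-5
FM_WEIGHT_POWER = 2


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the missing artifact."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, in one serialisable object."""

    outdir: str = "syntevo_run"
    seed: int = 0
    # simulation scenario
    n_taxa: int = 6
    crown_age: float = 60.0
    sim: SimConfig = field(default_factory=SimConfig)
    hit_noise: float = 0.1
    n_families: int = 1000
    family_lambda: float = 0.05
    family_shift: tuple | None = None
    # analysis thresholds
    evalue_max: float = RBH_EVALUE_MAX
    min_genes: int = MIN_BLOCK_GENES
    max_gap: int = MAX_BLOCK_GAP
    max_inversions: int = MAX_BLOCK_INVERSIONS
    weight_power: float = FM_WEIGHT_POWER
    nonneg: bool = True
    n_perm: int = 1000
    double_time: bool = False  # use 2T path length instead of MRCA age

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        for name in ("evalue_max", "min_genes", "max_gap", "max_inversions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("family_shift") is not None:
            clade, mult = d["family_shift"]
            d["family_shift"] = [sorted(clade), mult]
        return d

    def digest(self) -> str:
        payload = self.to_dict()
        payload.pop("outdir", None)  # where a run lands is not provenance
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(outdir: Path, written: list):
    """Remove this stage's partial outputs if it raises."""

    class _Ctx:
        def __init__(self):
            self.files: list[Path] = []

        def path(self, name: str) -> Path:
            p = outdir / name
            self.files.append(p)
            return p

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is not None:
                for p in self.files:
                    p.unlink(missing_ok=True)
            else:
                written.extend(self.files)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the aggregated report.

    Artifacts are written under ``cfg.outdir``; the report is also
    stored there as ``report.json``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "tool": f"syntevo {__version__}",
        "config_sha": cfg.digest(),
        "seed": cfg.seed,
    }
    written: list = []
    report: dict = {"version": __version__, "config": cfg.to_dict(),
                    "config_sha": cfg.digest()}

    # -- stage 1: simulate ------------------------------------------------
    with _stage(outdir, written) as st:
        tree = simulate_tree(cfg.n_taxa, cfg.crown_age, cfg.seed)
        tree.write(st.path("tree.nwk"))
        genomes, truth = simulate_genomes(tree, cfg.sim)
        for sp, ann in sorted(genomes.items()):
            write_annotation(ann, st.path(f"genes_{sp}.tsv"), meta)
        write_truth(truth, st.path("truth.json"))
        hits = simulate_hit_tables(genomes, truth, cfg.hit_noise, cfg.seed)
        for (a, b), table in sorted(hits.items()):
            write_hit_table(table, st.path(f"hits_{a}_vs_{b}.tsv"), meta)
        logger.info("simulated %d genomes on a %g MY tree",
                    len(genomes), tree.root_age)

    # -- stage 2: orthology ----------------------------------------------
    with _stage(outdir, written) as st:
        species = sorted(genomes)
        pairsets = {}
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                ps = rbh_pairs(hits[(a, b)], hits[(b, a)], cfg.evalue_max)
                pairsets[frozenset([a, b])] = ps
                write_pairset(ps, st.path(f"orthologs_{a}_{b}.tsv"), meta)
        n_links = {tuple(sorted(k)): len(v) for k, v in pairsets.items()}
        report["orthology"] = {"n_pairs_per_species_pair":
                               {f"{a}|{b}": n for (a, b), n in n_links.items()}}
        logger.info("RBH links per pair: %s", n_links)

    # -- stage 3: synteny -------------------------------------------------
    with _stage(outdir, written) as st:
        loss_dm, rate_dm = pairwise_loss_matrix(
            genomes, pairsets, tree,
            cfg.min_genes, cfg.max_gap, cfg.max_inversions, cfg.double_time,
        )
        write_distance_matrix(loss_dm, st.path("synteny_loss.phylip"), meta)
        write_distance_matrix(rate_dm, st.path("synteny_rates.phylip"), meta)
        p_s = {}
        for i, a in enumerate(species):
            for b in species[i + 1 :]:
                T = tree.mrca_age(a, b) * (2.0 if cfg.double_time else 1.0)
                stx = pair_synteny_stats(
                    genomes[a], genomes[b], pairsets[frozenset([a, b])], T,
                    cfg.min_genes, cfg.max_gap, cfg.max_inversions,
                )
                p_s[f"{a}|{b}"] = stx.p_s
                write_blocks(stx.blocks, genomes,
                             st.path(f"blocks_{a}_{b}.tsv"), meta)
        report["synteny"] = {
            "p_s": p_s,
            "loss_matrix": loss_dm.values.tolist(),
            "rate_matrix": rate_dm.values.tolist(),
            "species": loss_dm.names,
            "thresholds": dict(
                min_genes=cfg.min_genes, max_gap=cfg.max_gap,
                max_inversions=cfg.max_inversions,
            ),
        }

    # -- stage 4: branch fit ----------------------------------------------
    with _stage(outdir, written) as st:
        fit = fit_branch_lengths(tree, loss_dm, cfg.weight_power, cfg.nonneg)
        rates = branch_rates(fit, tree)
        with open(st.path("branch_rates.tsv"), "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            rates.to_csv(fh, sep="\t", index=False)
        report["treefit"] = {
            "rss": fit.rss,
            "branches": rates.to_dict(orient="records"),
        }

    # -- stage 5: family dynamics ------------------------------------------
    with _stage(outdir, written) as st:
        counts = simulate_family_counts(
            tree, cfg.n_families, cfg.family_lambda, cfg.family_shift, cfg.seed
        )
        write_family_counts(counts, st.path("family_counts.tsv"), meta)
        dyn = permutation_percentiles(counts, tree, cfg.n_perm, cfg.seed)
        with open(st.path("node_dynamics.tsv"), "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            dyn.to_csv(fh, sep="\t", index=False)
        report["famdyn"] = dyn.to_dict(orient="records")

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    report["report_path"] = str(report_path)
    return report
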