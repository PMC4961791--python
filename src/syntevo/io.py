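"""Readers and writers for the package's plain-text interchange formats.

Gene annotations and ortholog pair sets travel as 5-/2-column TSV, hit
tables as BLAST tabular (outfmt 6), distance matrices as PHYLIP square
matrices, trees as newick, truth sets as JSON.  Writers can prepend
``# key: value`` metadata header lines; readers skip ``#`` comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .famdyn import FamilyCounts
from .orthology import OUTFMT6_COLUMNS, HitTable, OrthologPairSet
from .synteny import COLUMNS as GENE_COLUMNS
from .synteny import GenomeAnnotation, SyntenyBlock
from .treefit import DistanceMatrix

__all__ = [
    "write_annotation", "read_annotation",
    "write_hit_table", "read_hit_table",
    "write_pairset", "read_pairset",
    "write_family_counts", "read_family_counts",
    "write_distance_matrix", "read_distance_matrix",
    "write_blocks",
    "write_truth", "read_truth",
]


def _header_lines(metadata: dict | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in metadata.items())


def _write_df(df: pd.DataFrame, path, metadata=None, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(metadata))
        df.to_csv(fh, sep="\t", index=index)


def write_annotation(ann: GenomeAnnotation, path, metadata=None) -> None:
    _write_df(ann.df, path, metadata)


def read_annotation(path, species: str | None = None) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#")
    if species is None:
        species = Path(path).stem
    return GenomeAnnotation(species=species, df=df[GENE_COLUMNS])


def write_hit_table(hits: HitTable, path, metadata=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(metadata))
        hits.df.to_csv(fh, sep="\t", index=False, header=False)


def read_hit_table(path, query_species: str, subject_species: str) -> HitTable:
    df = pd.read_csv(path, sep="\t", comment="#", names=OUTFMT6_COLUMNS)
    return HitTable(query_species, subject_species, df)


def write_pairset(pairs: OrthologPairSet, path, metadata=None) -> None:
    sa, sb = pairs.species
    df = pd.DataFrame(
        sorted(pairs.links), columns=[f"gene_{sa}", f"gene_{sb}"]
    )
    meta = {"species_a": sa, "species_b": sb}
    meta.update(metadata or {})
    _write_df(df, path, meta)


def read_pairset(path) -> OrthologPairSet:
    species = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, val = line[2:].partition(":")
            species[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    links = set(map(tuple, df.values))
    return OrthologPairSet(
        species=(species["species_a"], species["species_b"]), links=links
    )


def write_family_counts(counts: FamilyCounts, path, metadata=None) -> None:
    _write_df(counts.df.rename_axis("family"), path, metadata, index=True)


def read_family_counts(path) -> FamilyCounts:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="family")
    return FamilyCounts(df=df)


def write_distance_matrix(dm: DistanceMatrix, path, metadata=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(metadata))
        fh.write(dm.to_phylip())


def read_distance_matrix(path) -> DistanceMatrix:
    text = "\n".join(
        ln for ln in Path(path).read_text().splitlines()
        if not ln.startswith("#")
    )
    return DistanceMatrix.from_phylip(text)


def write_blocks(blocks: list[SyntenyBlock], annotations: dict, path,
                 metadata=None) -> None:
    """Blocks as BED-pair-like TSV with bp extents in both genomes."""
    rows = []
    for blk in blocks:
        sp_a, sp_b = blk.species
        coords_a = annotations[sp_a].df.set_index("gene_id")
        coords_b = annotations[sp_b].df.set_index("gene_id")
        genes_a = [an.gene_a for an in blk.anchors]
        genes_b = [an.gene_b for an in blk.anchors]
        rows.append(
            dict(
                scaffold_a=blk.scaffold_a,
                start_a=int(coords_a.loc[genes_a, "start"].min()),
                end_a=int(coords_a.loc[genes_a, "end"].max()),
                scaffold_b=blk.scaffold_b,
                start_b=int(coords_b.loc[genes_b, "start"].min()),
                end_b=int(coords_b.loc[genes_b, "end"].max()),
                n_anchors=blk.n_anchors,
                inversions=blk.inversions,
            )
        )
    _write_df(pd.DataFrame(rows), path, metadata)


def write_truth(truth, path) -> None:
    payload = {
        "ortholog_map": truth.ortholog_map,
        "event_log": [list(ev) for ev in truth.event_log],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path):
    from .simulate import TruthSet

    payload = json.loads(Path(path).read_text())
    return TruthSet(
        ortholog_map=payload["ortholog_map"],
        event_log=[tuple(ev) for ev in payload["event_log"]],
    )
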