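import numpy as np
import pandas as pd
import pytest

from syntevo import DatedTree, GenomeAnnotation, OrthologPairSet


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with the inner nodes at 10 MY and the root at 20 MY."""
    return DatedTree.from_newick("((A:10,B:10):10,(C:10,D:10):10);")


@pytest.fixture
def cherry_tree():
    return DatedTree.from_newick("(A:10,B:10);")


def make_annotation(species, gene_order, scaffold="s1", strands=None):
    """Annotation from an explicit gene order on one scaffold."""
    strands = strands or ["+"] * len(gene_order)
    rows = [
        (g, scaffold, 1 + i * 1100, 1000 + i * 1100, st)
        for i, (g, st) in enumerate(zip(gene_order, strands))
    ]
    return GenomeAnnotation(
        species=species,
        df=pd.DataFrame(
            rows, columns=["gene_id", "scaffold", "start", "end", "strand"]
        ),
    )


def identity_pairs(sp_a, sp_b, genes):
    """Pair set linking gene g in A to gene g in B."""
    return OrthologPairSet(species=(sp_a, sp_b), links={(g, g) for g in genes})


@pytest.fixture
def rng():
    return np.random.default_rng(20160720)
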