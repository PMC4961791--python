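"""Dated rooted phylogenies.

A :class:`DatedTree` wraps a rooted :class:`dendropy.Tree` whose edge
lengths are in millions of years (MY) and caches node ages (time before
present), clade leaf sets and MRCA lookups.  Leaves are at age 0; every
parent is older than its children.  Trees used for genome simulation and
branch fitting are ultrametric, but only the age invariants are enforced.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import dendropy

__all__ = ["DatedTree", "branch_key"]

_AGE_TOL = 1e-6


def branch_key(leaf_names: Iterable[str]) -> int:
    """Stable integer identifier for a branch, from the clade below it.

    Hashing the sorted leaf names keeps per-branch random streams
    unchanged when unrelated parts of a simulation are reconfigured.
    """
    blob = ",".join(sorted(leaf_names)).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:6], "big")


class DatedTree:
    """Rooted phylogeny with node ages in MY."""

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
            raise ValueError("tree must be rooted with at least one split")
        self._tree = tree
        self._index()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "DatedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- indexing ----------------------------------------------------------

    def _index(self) -> None:
        depth = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                length = node.edge.length if node.edge.length is not None else 0.0
                depth[node] = depth[node.parent_node] + length
        leaf_depths = [depth[lf] for lf in self._tree.leaf_node_iter()]
        root_age = max(leaf_depths)
        self._leafset = {}
        for node in self._tree.postorder_node_iter():
            age = root_age - depth[node]
            node.age = 0.0 if node.is_leaf() and abs(age) < _AGE_TOL else age
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("every leaf must be labelled")
                self._leafset[node] = frozenset([node.taxon.label])
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.child_nodes())
                )
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                if child.age > node.age + _AGE_TOL:
                    raise ValueError("child older than parent; branch lengths invalid")
        names = sorted(self._leafset[self._tree.seed_node])
        if len(names) != len(self._tree.leaf_nodes()):
            raise ValueError("duplicate leaf names")
        self._leaf_names = names
        self._by_clade = {v: k for k, v in self._leafset.items()}

    # -- queries -----------------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        """Leaf labels in sorted order (the canonical matrix ordering)."""
        return list(self._leaf_names)

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self.root.age

    def clade(self, node: dendropy.Node) -> frozenset[str]:
        return self._leafset[node]

    def node_for_clade(self, leaves: Iterable[str]) -> dendropy.Node:
        key = frozenset(leaves)
        try:
            return self._by_clade[key]
        except KeyError:
            raise KeyError(f"no node subtends exactly {sorted(key)}") from None

    def mrca(self, names: Sequence[str]) -> dendropy.Node:
        want = frozenset(names)
        if not want <= frozenset(self._leaf_names):
            missing = sorted(want - frozenset(self._leaf_names))
            raise KeyError(f"leaves not in tree: {missing}")
        best = self.root
        for node in self._tree.postorder_node_iter():
            if want <= self._leafset[node] and len(self._leafset[node]) < len(
                self._leafset[best]
            ):
                best = node
        return best

    def mrca_age(self, a: str, b: str) -> float:
        return self.mrca([a, b]).age

    def edges(self) -> list[tuple[dendropy.Node, float, float, frozenset[str]]]:
        """All non-root edges as (child node, parent age, child age, clade)."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append(
                    (node, node.parent_node.age, node.age, self._leafset[node])
                )
        return out

    def internal_clades(self, include_root: bool = False) -> list[frozenset[str]]:
        out = []
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node is self.root and not include_root:
                continue
            out.append(self._leafset[node])
        return out

    def preorder(self):
        return self._tree.preorder_node_iter()

    def __len__(self) -> int:
        return len(self._leaf_names)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DatedTree({len(self)} leaves, root age {self.root_age:g} MY)"
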