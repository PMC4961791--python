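"""Weighted least-squares branch-length fitting on a fixed topology.

Given a matrix of pairwise evolutionary distances (here: synteny loss
between species pairs) and a rooted dated tree, estimate a non-negative
"amount" for every branch so that path sums through the tree reproduce
the observed distances as closely as possible — the Fitch–Margoliash
criterion

    minimise  sum_{i<j}  w_ij (d_ij - path_ij(b))^2,   w_ij = d_ij^(-P)

with ``P`` the weighting power (2 by default, the classic choice; pairs
with d_ij = 0 get unit weight).  Because the problem is linear in the
branch lengths it is solved as a (weighted, optionally non-negative)
linear least-squares system on the pair-by-branch path-incidence matrix.

Root caveat: path lengths between leaves never separate the two branches
incident to the root — only their sum is identifiable.  The sum is fitted
as a single parameter and reported split proportionally to the two
branches' time durations, flagged in the output table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .trees import DatedTree

__all__ = ["DistanceMatrix", "BranchFit", "fit_branch_lengths", "branch_rates"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over named leaves."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match the number of names")
        if len(set(self.names)) != n:
            raise ValueError("duplicate names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def reorder(self, names: list[str]) -> "DistanceMatrix":
        idx = [self.names.index(n) for n in names]
        return DistanceMatrix(list(names), self.values[np.ix_(idx, idx)])

    # PHYLIP square format: taxon count line, then one row per taxon.
    def to_phylip(self) -> str:
        lines = [f"{len(self.names):5d}"]
        for name, row in zip(self.names, self.values):
            cells = " ".join(f"{v:.10f}" for v in row)
            lines.append(f"{name:<12s}{cells}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        rows = [ln.split() for ln in text.strip().splitlines() if ln.strip()]
        n = int(rows[0][0])
        names, vals = [], []
        for row in rows[1 : n + 1]:
            names.append(row[0])
            vals.append([float(x) for x in row[1 : n + 1]])
        return cls(names, np.array(vals))


def _clade_label(clade: frozenset[str]) -> str:
    return ",".join(sorted(clade))


@dataclass
class BranchFit:
    """Fitted per-branch amounts on a dated topology."""

    table: pd.DataFrame  # clade, parent_age, child_age, duration, loss, root_pair
    rss: float
    root_pair_loss: float
    weight_power: float
    nonneg: bool
    _loss_by_clade: dict = field(repr=False, default_factory=dict)

    def loss_for(self, leaves) -> float:
        return self._loss_by_clade[frozenset(leaves)]

    def fitted_distances(self, tree: DatedTree) -> DistanceMatrix:
        """Reconstruct the pairwise matrix implied by the fitted branches."""
        names = tree.leaf_names
        n = len(names)
        out = np.zeros((n, n))
        edges = tree.edges()
        for i in range(n):
            for j in range(i + 1, n):
                d = 0.0
                for _, _, _, clade in edges:
                    if (names[i] in clade) != (names[j] in clade):
                        d += self._loss_by_clade[clade]
                out[i, j] = out[j, i] = d
        return DistanceMatrix(names, out)


def fit_branch_lengths(
    topology: DatedTree,
    D: DistanceMatrix,
    weight_power: float = 2.0,
    nonneg: bool = True,
) -> BranchFit:
    """Fit branch amounts to ``D`` on the fixed ``topology``.

    Parameters
    ----------
    topology
        Rooted dated tree whose leaf set matches ``D``.
    D
        Observed symmetric distances.
    weight_power
        P in w_ij = d_ij^(-P); 0 gives ordinary least squares.
    nonneg
        Constrain branch amounts to be >= 0 (active-set NNLS solve).
    """
    names = topology.leaf_names
    if set(names) != set(D.names):
        raise ValueError("leaf sets of topology and distance matrix differ")
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 leaves to fit branch lengths")
    D = D.reorder(names)

    edges = topology.edges()
    root_children = [e for e in edges if e[0].parent_node is topology.root]
    other = [e for e in edges if e[0].parent_node is not topology.root]
    # parameters: one per non-root edge, plus one shared root-pair parameter
    params = [e[3] for e in other]
    n_par = len(params) + 1
    root_side = root_children[0][3]  # clade of one root child

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), n_par))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        a, b = names[i], names[j]
        d[r] = D.values[i, j]
        for c, clade in enumerate(params):
            if (a in clade) != (b in clade):
                A[r, c] = 1.0
        if (a in root_side) != (b in root_side):
            A[r, -1] = 1.0

    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d ** (-float(weight_power)), 1.0)
    sw = np.sqrt(w)
    Aw = A * sw[:, None]
    dw = d * sw

    if nonneg:
        b_hat, _ = nnls(Aw, dw)
    else:
        b_hat, *_ = np.linalg.lstsq(Aw, dw, rcond=None)

    resid = d - A @ b_hat
    rss = float(np.sum(w * resid**2))

    root_sum = float(b_hat[-1])
    durs = [pa - ca for _, pa, ca, _ in root_children]
    tot = sum(durs)
    shares = [du / tot if tot > 0 else 0.5 for du in durs]

    loss_by_clade = {clade: float(v) for clade, v in zip(params, b_hat[:-1])}
    rows = []
    for (_, pa, ca, clade), v in zip(other, b_hat[:-1]):
        rows.append(
            dict(
                clade=_clade_label(clade),
                parent_age=pa,
                child_age=ca,
                duration=pa - ca,
                loss=float(v),
                root_pair=False,
            )
        )
    for (node, pa, ca, clade), share in zip(root_children, shares):
        loss_by_clade[clade] = root_sum * share
        rows.append(
            dict(
                clade=_clade_label(clade),
                parent_age=pa,
                child_age=ca,
                duration=pa - ca,
                loss=root_sum * share,
                root_pair=True,
            )
        )
    table = pd.DataFrame(rows)
    return BranchFit(
        table=table,
        rss=rss,
        root_pair_loss=root_sum,
        weight_power=float(weight_power),
        nonneg=nonneg,
        _loss_by_clade=loss_by_clade,
    )


def branch_rates(fit: BranchFit, dated: DatedTree) -> pd.DataFrame:
    """Convert fitted branch losses to per-MY rates.

    Branches of zero time duration cannot carry a rate; they are reported
    as missing with a warning.
    """
    clades = {_clade_label(c) for c in fit._loss_by_clade}
    tree_clades = {_clade_label(e[3]) for e in dated.edges()}
    if clades != tree_clades:
        raise ValueError("fit and tree topologies differ")
    table = fit.table.copy()
    zero = table["duration"] <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} branch(es) of zero duration: rate reported as NaN"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["rate_per_my"] = np.where(
            zero, np.nan, table["loss"] / table["duration"]
        )
    return table
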