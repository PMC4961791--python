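"""Statistical procedures used alongside the synteny analyses.

Rank tests (exact Mann–Whitney by enumeration, tie-corrected
Kruskal–Wallis, Steel–Dwass pairwise post-hoc), a two-sided exact
binomial test of equal counts, simulation-based phylogenetic ANOVA
(Brownian-motion null on the tree, Garland-style), and pepstats-style
protein properties (isoelectric point with the EMBOSS pK table, average
residue weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from scipy import stats as sps

from .trees import DatedTree

__all__ = [
    "TraitVector",
    "TestResult",
    "mann_whitney",
    "kruskal_wallis",
    "steel_dwass",
    "binomial_equal_test",
    "phylo_anova",
    "protein_pi",
    "avg_residue_weight",
]


@dataclass
class TraitVector:
    """Per-leaf numeric trait values and group labels."""

    values: dict
    groups: dict

    def __post_init__(self):
        if set(self.values) != set(self.groups):
            raise ValueError("every leaf needs exactly one value and one group")


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n: dict

    def __post_init__(self):
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# rank tests

_EXACT_LIMIT = 16  # max pooled size for exact MWU enumeration


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x_i < y_j) + 0.5 #(x_i = y_j)."""
    less = (x[:, None] < y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U test.

    The statistic reported is min(U, n1*n2 - U).  With
    ``method='auto'`` an exact p-value is computed by enumerating all
    label assignments when n1 + n2 <= 16 and the data are tie-free
    (two-sided = doubled lower tail, capped at 1); otherwise a
    tie-corrected normal approximation with continuity correction is
    used.  ``method`` may force 'exact' or 'normal'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    u_min = min(u, n1 * n2 - u)
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == pooled.size
    if method == "auto":
        method = "exact" if (n1 + n2 <= _EXACT_LIMIT and tie_free) else "normal"
    if method == "exact":
        if not tie_free:
            raise ValueError("exact enumeration requires tie-free data")
        order = np.argsort(pooled)
        ranks = np.empty(pooled.size, dtype=int)
        ranks[order] = np.arange(pooled.size)
        tail = 0
        total = 0
        offset = n1 * (n1 - 1) // 2
        for combo in combinations(range(n1 + n2), n1):
            # U for this assignment from the rank sum of the x side
            u_c = sum(combo) - offset
            u_c = min(u_c, n1 * n2 - u_c)
            tail += u_c <= u_min
            total += 1
        # doubled one-sided tail of the unfolded statistic == folded tail
        p = min(1.0, tail / total)
        label = "Mann-Whitney U (exact enumeration)"
    elif method == "normal":
        mean = n1 * n2 / 2.0
        N = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum())
        var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var <= 0:
            return TestResult(u_min, 1.0, "Mann-Whitney U (degenerate)",
                              {"n1": n1, "n2": n2})
        cc = min(abs(u - mean), 0.5)
        z = (abs(u - mean) - cc) / math.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(z))
        label = "Mann-Whitney U (normal approximation)"
    else:
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    return TestResult(u_min, p, label, {"n1": n1, "n2": n2})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with midrank ties and tie-correction divisor.

    p-value from the chi-square approximation with k - 1 degrees of
    freedom.  All-identical data give H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r = ranks[pos : pos + g.size]
        h += r.sum() ** 2 / g.size
        pos += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((counts**3 - counts).sum()) / (N**3 - N)
    if correction <= 0:  # every value identical
        return TestResult(0.0, 1.0, "Kruskal-Wallis H",
                          {f"g{i+1}": g.size for i, g in enumerate(groups)})
    h /= correction
    p = float(sps.chi2.sf(h, len(groups) - 1))
    return TestResult(h, p, "Kruskal-Wallis H",
                      {f"g{i+1}": g.size for i, g in enumerate(groups)})


def steel_dwass(groups, labels=None) -> pd.DataFrame:
    """Steel–Dwass all-pairs post-hoc comparisons.

    Each pair of groups is compared on its own pooled midranks; the
    standardized rank-sum statistic is referred to the studentized range
    distribution with k groups and infinite degrees of freedom
    (adjusted p = Pr(Q >= |z| * sqrt(2))).  Large-sample approximation;
    interpret with care when any group has fewer than 8 observations.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Steel-Dwass needs >= 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 observations")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    out = np.full((k, k), np.nan)
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        ni, nj = gi.size, gj.size
        nij = ni + nj
        ranks = sps.rankdata(np.concatenate([gi, gj]))
        ri = ranks[:ni].sum()
        expect = ni * (nij + 1) / 2.0
        var = ni * nj / (nij * (nij - 1.0)) * float(
            (ranks**2).sum() - nij * (nij + 1.0) ** 2 / 4.0
        )
        z = 0.0 if var <= 0 else (ri - expect) / math.sqrt(var)
        p = float(sps.studentized_range.sf(abs(z) * math.sqrt(2.0), k, np.inf))
        out[i, j] = out[j, i] = min(1.0, p)
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# binomial test of equal counts

def binomial_equal_test(k: int, n: int) -> TestResult:
    """Two-sided exact binomial test of equal counts (p = 1/2).

    Minimum-likelihood method in exact integer arithmetic: the p-value
    sums Pr(m) over all outcomes m no more probable than the observed k.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    ref = math.comb(n, k)
    num = sum(math.comb(n, m) for m in range(n + 1) if math.comb(n, m) <= ref)
    p = min(1.0, num / 2**n)
    return TestResult(float(k), p, "binomial test (equal counts)", {"n": n})


# ---------------------------------------------------------------------------
# phylogenetic ANOVA

def _phylo_covariance(tree: DatedTree) -> tuple[list, np.ndarray]:
    names = tree.leaf_names
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    C = np.zeros((n, n))
    root_age = tree.root_age
    for _, parent_age, child_age, clade in tree.edges():
        members = np.array([idx[nm] for nm in clade])
        C[np.ix_(members, members)] += parent_age - child_age
    # shared path of a leaf with itself is its full root-to-tip depth
    for nm, i in idx.items():
        C[i, i] = root_age - tree.node_for_clade([nm]).age
    return names, C


def _anova_f(X: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """Classical one-way ANOVA F; X is (n,) or (n_sim, n)."""
    X = np.atleast_2d(X)
    n = X.shape[1]
    k = len(masks)
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for m in masks:
        gm = X[:, m].mean(axis=1, keepdims=True)
        ssb += m.sum() * (gm[:, 0] - grand[:, 0]) ** 2
        ssw += ((X[:, m] - gm) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return f


def phylo_anova(
    tree: DatedTree, traits: TraitVector, n_sim: int = 1000, seed: int = 0
) -> TestResult:
    """Phylogenetic ANOVA with a Brownian-motion simulation null.

    The observed statistic is the ordinary one-way ANOVA F of the trait
    across groups.  Its null distribution is obtained by simulating BM
    on the tree ``n_sim`` times — at the REML-style rate estimated from
    the data around the phylogenetic mean — and recomputing F with the
    same group labels; p = (1 + #{F_sim >= F_obs}) / (n_sim + 1).
    """
    names = tree.leaf_names
    if set(traits.values) != set(names):
        raise ValueError("trait leaves do not match tree leaves")
    x = np.array([traits.values[nm] for nm in names], dtype=float)
    labels = [traits.groups[nm] for nm in names]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    masks = [np.array([lb == u for lb in labels]) for u in uniq]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("every group needs >= 2 leaves")
    if np.allclose(x, x[0]):
        raise ValueError("zero total variance: ANOVA undefined")

    _, C = _phylo_covariance(tree)
    Cinv = np.linalg.inv(C)
    one = np.ones(len(x))
    mu = float(one @ Cinv @ x / (one @ Cinv @ one))
    resid = x - mu
    sigma2 = float(resid @ Cinv @ resid) / (len(x) - 1)

    f_obs = float(_anova_f(x, masks)[0])
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n_sim, len(x)))
    sims = math.sqrt(sigma2) * Z @ L.T
    f_sim = _anova_f(sims, masks)
    p = (1.0 + float((f_sim >= f_obs).sum())) / (n_sim + 1.0)
    return TestResult(
        f_obs, p, "phylogenetic ANOVA (BM simulation null)",
        {u: int(m.sum()) for u, m in zip(uniq, masks)},
    )


# ---------------------------------------------------------------------------
# protein properties (pepstats-style)

# EMBOSS pK table
_PK_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PK_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
_WATER = 18.0153


def _check_sequence(seq: str, skip_unknown: bool) -> str:
    seq = seq.upper()
    bad = set(seq) - _RESIDUES
    if bad:
        if not skip_unknown:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        seq = "".join(c for c in seq if c in _RESIDUES)
    if not seq:
        raise ValueError("empty sequence")
    return seq


def net_charge(seq: str, ph: float, skip_unknown: bool = False) -> float:
    """Net protein charge at ``ph`` from the EMBOSS pK table."""
    seq = _check_sequence(seq, skip_unknown)
    pos = [_PK_POSITIVE["Nterm"]] + [
        _PK_POSITIVE[c] for c in seq if c in _PK_POSITIVE
    ]
    neg = [_PK_NEGATIVE["Cterm"]] + [
        _PK_NEGATIVE[c] for c in seq if c in _PK_NEGATIVE
    ]
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pk - ph)) for pk in neg)
    return charge


def protein_pi(
    seq: str, tol: float = 1e-6, skip_unknown: bool = False
) -> float:
    """Isoelectric point: the pH of zero net charge, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges; the
    returned pH satisfies |charge| < ``tol``.
    """
    seq = _check_sequence(seq, skip_unknown)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(seq, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def avg_residue_weight(seq: str, skip_unknown: bool = False) -> float:
    """Mean residue mass in Da (monomer average mass minus water)."""
    seq = _check_sequence(seq, skip_unknown)
    mw = molecular_weight(seq, seq_type="protein")
    return (mw - _WATER) / len(seq)
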