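"""Independent reference implementations used only to check the package."""

from itertools import combinations

import numpy as np


def descending_runs(seq):
    """Count maximal strictly descending runs of length >= 2, directly."""
    runs, i, n = 0, 0, len(seq)
    while i < n - 1:
        if seq[i + 1] < seq[i]:
            j = i + 1
            while j + 1 < n and seq[j + 1] < seq[j]:
                j += 1
            runs += 1
            i = j
        else:
            i += 1
    return runs


def oracle_blocks(ga, gb, pairs, min_genes=5, max_gap=4, max_inversions=5):
    """Exhaustive syntenic-block reference.

    Rebuilds anchors from the annotations, then enumerates *all* legal
    contiguous anchor intervals per scaffold pair (an interval is legal
    when every adjacent anchor pair satisfies the two-genome gap rule),
    keeps the maximal ones, and applies the size and inversion filters.
    Returns the block partition as a set of gene_a tuples.
    """

    def order_map(ann):
        out = {}
        for scaffold, sub in ann.df.groupby("scaffold"):
            for i, (_, row) in enumerate(
                sub.sort_values(["start", "gene_id"]).iterrows()
            ):
                out[row["gene_id"]] = (scaffold, i)
        return out

    oa, ob = order_map(ga), order_map(gb)
    groups = {}
    for a_gene, b_gene in pairs.oriented(ga.species, gb.species):
        (sca, ia), (scb, ib) = oa[a_gene], ob[b_gene]
        groups.setdefault((sca, scb), []).append((ia, ib, a_gene))

    result = set()
    for anchors in groups.values():
        anchors.sort()
        n = len(anchors)

        def ok(k):
            gap_a = anchors[k + 1][0] - anchors[k][0] - 1
            gap_b = abs(anchors[k + 1][1] - anchors[k][1]) - 1
            return gap_a <= max_gap and gap_b <= max_gap

        legal = {
            (i, j)
            for i in range(n)
            for j in range(i, n)
            if all(ok(k) for k in range(i, j))
        }
        maximal = [
            (i, j)
            for (i, j) in legal
            if not any(
                p <= i and j <= q and (p, q) != (i, j) for (p, q) in legal
            )
        ]
        for i, j in maximal:
            chain = anchors[i : j + 1]
            if len(chain) < min_genes:
                continue
            if descending_runs([b for _, b, _ in chain]) > max_inversions:
                continue
            result.add(tuple(g for _, _, g in chain))
    return result


def brute_force_mwu(x, y):
    """Exact two-sided Mann-Whitney p by direct enumeration over values.

    Counts U = #(x_i < y_j) for every split of the pooled values, with no
    rank shortcut; two-sided p doubles the lower tail of the folded
    statistic, capped at 1.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_of(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi < yj)

    u_obs = u_of(x, y)
    u_obs = min(u_obs, n1 * n2 - u_obs)
    tail = total = 0
    for idx in combinations(range(n1 + n2), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in range(n1 + n2) if i in chosen]
        ys = [pooled[i] for i in range(n1 + n2) if i not in chosen]
        u = u_of(xs, ys)
        tail += min(u, n1 * n2 - u) <= u_obs
        total += 1
    return u_obs, min(1.0, tail / total)


def additive_distances(tree, lengths):
    """Pairwise leaf distances from per-clade branch lengths.

    ``lengths`` maps each non-root edge's clade (frozenset of leaves) to
    its length; a leaf pair's distance sums lengths of edges separating
    them.
    """
    names = tree.leaf_names
    n = len(names)
    D = np.zeros((n, n))
    edges = [(clade, lengths[clade]) for _, _, _, clade in tree.edges()]
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(
                v for clade, v in edges if (names[i] in clade) != (names[j] in clade)
            )
            D[i, j] = D[j, i] = d
    return D
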