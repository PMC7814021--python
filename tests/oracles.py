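"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by the most transparent possible
method (quadratic scans, union-find, exhaustive enumeration) and stays
independent of the implementation path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_pairs(set_a, set_b):
    """All overlapping (a, b, bp) pairs by a quadratic scan."""
    out = []
    for a in set_a:
        ia = a.interval if hasattr(a, "interval") else a
        for b in set_b:
            ib = b.interval if hasattr(b, "interval") else b
            if ia.chrom != ib.chrom:
                continue
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov >= 1:
                out.append((a, b, ov))
    out.sort(key=lambda t: (
        (t[0].interval if hasattr(t[0], "interval") else t[0]).chrom,
        (t[0].interval if hasattr(t[0], "interval") else t[0]).start,
        (t[0].interval if hasattr(t[0], "interval") else t[0]).end,
        (t[1].interval if hasattr(t[1], "interval") else t[1]).start,
    ))
    return out


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def union_find_stitch(intervals, stitch_distance):
    """Partition intervals by chained gaps <= stitch_distance via pairwise
    union-find over all pairs."""
    uf = UnionFind(len(intervals))
    for i, a in enumerate(intervals):
        for j, b in enumerate(intervals):
            if i >= j or a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= stitch_distance:
                uf.union(i, j)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(uf.find(i), []).append(i)
    return sorted(
        tuple(sorted(g)) for g in groups.values()
    )


def overlap_components(intervals):
    """Connected components of the >=1bp overlap graph via union-find."""
    uf = UnionFind(len(intervals))
    for i, a in enumerate(intervals):
        for j, b in enumerate(intervals):
            if i >= j or a.chrom != b.chrom:
                continue
            if min(a.end, b.end) - max(a.start, b.start) >= 1:
                uf.union(i, j)
    groups = {}
    for i in range(len(intervals)):
        groups.setdefault(uf.find(i), []).append(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = p[i] * m / rank_from_top
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def exhaustive_maximal_cliques(nodes, undirected_edges):
    """All maximal cliques of size >= 2 by testing every subset."""
    nodes = sorted(nodes)
    edge_set = {frozenset(e) for e in undirected_edges}

    def is_clique(sub):
        return all(
            frozenset((a, b)) in edge_set
            for a, b in itertools.combinations(sub, 2)
        )

    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            if any(
                other not in sub and is_clique(tuple(sorted(set(sub) | {other})))
                for other in nodes
            ):
                continue  # extendable, not maximal
            cliques.append(tuple(sorted(sub)))
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def exhaustive_word_scores(pwm, background=None):
    """Score every 4^w word by direct per-position product evaluation."""
    from crckit.sequences import BASES

    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = 0.0
        for pos, b in enumerate(word):
            s += np.log2(pwm.probs[pos, b] / bg[b])
        scores["".join(BASES[b] for b in word)] = s
    return scores


def median_of_ratios(mat):
    """Direct median-of-ratios size factors (geometric mean 1)."""
    mat = np.asarray(mat, dtype=float)
    keep = np.all(mat > 0, axis=1)
    sub = mat[keep]
    geo = np.exp(np.mean(np.log(sub), axis=1))
    sf = np.array([np.median(sub[:, j] / geo) for j in range(mat.shape[1])])
    return sf / np.exp(np.mean(np.log(sf)))
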