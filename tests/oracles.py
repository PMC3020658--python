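"""Independent reference implementations used only for cross-checking.

These deliberately avoid the code paths they validate: a quadratic-time
Gotoh DP for local alignment scores, a hand-rolled union-find for connected
components, normal-equation least squares, and a direct t-statistic/CDF
evaluation.
"""

from __future__ import annotations

import itertools
import math


def sw_affine_score(seq_a: str, seq_b: str, score_fn, gap_open: float,
                    gap_extend: float) -> float:
    """Smith-Waterman with affine gaps; a gap of length k costs open + k*extend."""
    n, m = len(seq_a), len(seq_b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq_a (move in b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in seq_b (move in a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + score_fn(seq_a[i - 1], seq_b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> set[frozenset]:
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def components_oracle(edges, universe) -> set[frozenset]:
    uf = UnionFind(universe)
    for edge in edges:
        a, b = tuple(edge)
        uf.union(a, b)
    return uf.components()


def ols_normal_equations(x, y):
    """Slope, intercept and R^2 from the closed-form normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def t_test_oracle(values, observed):
    """Two-tailed one-sample t-test by direct formula + reference t CDF."""
    from scipy.stats import t as t_dist

    m = len(values)
    mean = sum(values) / m
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (m - 1))
    t_stat = (mean - observed) / (sd / math.sqrt(m))
    p = 2.0 * t_dist.sf(abs(t_stat), m - 1)
    return t_stat, p


def brute_force_rbh(tables, iso_a, iso_b, threshold):
    """Re-check the three RBH conditions for every protein pair.

    ``tables`` maps directed isolate pairs to HitTable; the check scans the
    raw rows (no best-hit reduction helper) and applies the paper-style
    tie-break (E, then -bitscore, then subject ID) by explicit sorting.
    """
    def best_of(table):
        rows: dict = {}
        for r in table.frame.itertuples(index=False):
            rows.setdefault(r.qseqid, []).append((r.evalue, -r.bitscore, r.sseqid))
        return {q: sorted(v)[0] for q, v in rows.items()}

    ab = best_of(tables[(iso_a, iso_b)])
    ba = best_of(tables[(iso_b, iso_a)])
    edges = set()
    for q, (e_ab, _, s) in ab.items():
        if s in ba:
            e_ba, _, back = ba[s]
            if back == q and e_ab < threshold and e_ba < threshold:
                edges.add(frozenset((q, s)))
    return edges


def count_valid_sets_brute(species_counts: dict[str, int], k: int) -> int:
    """Enumerate every k-subset of concrete isolates and count multi-species ones."""
    isolates = [
        (sp, i) for sp, n in species_counts.items() for i in range(n)
    ]
    return sum(
        1 for combo in itertools.combinations(isolates, k)
        if len({sp for sp, _ in combo}) > 1
    )


def linkage_clades(labels, data):
    """UPGMA clades and heights via scipy's hierarchical clustering."""
    import numpy as np
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(np.asarray(data), checks=False), method="average")
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    clades = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[len(labels) + row_idx] = merged
        clades.append((merged, h / 2.0))
    return clades


def tree_clades(tree):
    """(leafset, height-above-leaves) for every internal node of an
    ultrametric skbio tree."""
    out = []

    def visit(node):
        if node.is_tip():
            return frozenset([node.name]), 0.0
        parts = [visit(c) for c in node.children]
        leaves = frozenset().union(*(p[0] for p in parts))
        height = parts[0][1] + node.children[0].length
        out.append((leaves, height))
        return leaves, height

    visit(tree)
    return out
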