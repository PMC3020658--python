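"""Distance metrics and clustering trees over isolates.

Three distance metrics mirror the three tree flavours of a gene-content
phylogeny study: marker distance (1 - identity/100), the Snel gene-content
distance 1 - S/P (S = shared orthologous groups, P = smaller proteome size),
and the average-unique-proteins measure used directly as a distance. Trees
are built either by UPGMA (ultrametric, size-weighted average linkage) or by
plain Saitou-Nei neighbour joining, and are returned as
:class:`skbio.tree.TreeNode` objects so Newick serialization and
Robinson-Foulds comparison come for free.
"""

from __future__ import annotations

import io as _io
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode


def snel_distance(shared: float, smaller_proteome: float) -> float:
    """1 - S/P; 0 for identical gene content, 1 for none shared."""
    if smaller_proteome <= 0:
        raise ValueError("smaller proteome size must be positive")
    if shared < 0 or shared > smaller_proteome:
        raise ValueError("shared groups must lie in [0, P]")
    return 1.0 - shared / smaller_proteome


def marker_distance(identity_percent: float) -> float:
    """1 - identity/100 for a percent identity in [0, 100]."""
    if not 0.0 <= identity_percent <= 100.0:
        raise ValueError("identity must be in [0, 100]")
    return 1.0 - identity_percent / 100.0


def avg_unique_distance(avg_unique: float) -> float:
    """The average-unique-proteins measure itself (non-negative, unbounded)."""
    if avg_unique < 0:
        raise ValueError("average unique proteins must be >= 0")
    return float(avg_unique)


class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    def __init__(self, labels: Sequence[str], data: np.ndarray) -> None:
        data = np.asarray(data, dtype=float)
        if data.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(data, data.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(data), 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(~np.isfinite(data)) or np.any(data < 0):
            raise ValueError("entries must be finite and non-negative")
        self.labels = list(labels)
        self.data = data

    @staticmethod
    def from_pairs(labels: Sequence[str], dist_fn) -> "DistanceMatrix":
        n = len(labels)
        data = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                data[i, j] = data[j, i] = dist_fn(labels[i], labels[j])
        return DistanceMatrix(labels, data)

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.data):
            lines.append(lab + "\t" + "\t".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"

    @staticmethod
    def read_tsv(text: str) -> "DistanceMatrix":
        rows = [ln.split("\t") for ln in text.rstrip("\n").split("\n")]
        header = rows[0]
        # labelled TSV has a leading empty cell; PHYLIP square has a count row
        if len(header) == 1 and header[0].strip().isdigit():
            labels = [r[0] for r in rows[1:]]
            data = [[float(v) for v in r[1:]] for r in rows[1:]]
        else:
            labels = header[1:]
            data = [[float(v) for v in r[1:]] for r in rows[1:]]
        return DistanceMatrix(labels, np.array(data))


def _tip(label: str) -> TreeNode:
    node = TreeNode(name=label)
    node.length = None
    return node


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Size-weighted average-linkage agglomeration into an ultrametric tree.

    At each step the closest cluster pair merges at height d/2; new distances
    are the member-count-weighted means. Ties are broken by the
    lexicographically smallest pair of cluster labels, where a cluster is
    labelled by its smallest leaf name, making the topology deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    dist = {
        frozenset((i, j)): dm.data[i, j]
        for i in range(n) for j in range(i + 1, n)
    }
    nodes = {i: _tip(lab) for i, lab in enumerate(dm.labels)}
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    names = {i: dm.labels[i] for i in range(n)}  # smallest leaf name
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            i, j = sorted(key)
            tag = tuple(sorted((names[i], names[j])))
            cand = (d, tag, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, i, j = best
        height = d / 2.0
        left, right = nodes[i], nodes[j]
        left.length = height - heights[i]
        right.length = height - heights[j]
        parent = TreeNode(children=[left, right])
        parent.length = None
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((new, k))] = (
                (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            )
        del dist[frozenset((i, j))]
        active -= {i, j}
        active.add(new)
        nodes[new] = parent
        sizes[new] = sizes[i] + sizes[j]
        heights[new] = height
        names[new] = min(names[i], names[j])
    root = nodes[active.pop()]
    root.length = None
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; exact on additive matrices.

    Returns an unrooted tree represented with a trifurcating root. Negative
    branch-length estimates on degenerate inputs are clamped at zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    ids = list(range(n))
    dist = {frozenset((i, j)): float(dm.data[i, j]) for i in range(n) for j in range(i + 1, n)}
    nodes = {i: _tip(lab) for i, lab in enumerate(dm.labels)}
    names = {i: dm.labels[i] for i in range(n)}
    next_id = n
    while len(ids) > 3:
        r = len(ids)
        totals = {i: sum(dist[frozenset((i, k))] for k in ids if k != i) for i in ids}
        best = None
        for a_pos in range(r):
            for b_pos in range(a_pos + 1, r):
                i, j = ids[a_pos], ids[b_pos]
                q = (r - 2) * dist[frozenset((i, j))] - totals[i] - totals[j]
                tag = tuple(sorted((names[i], names[j])))
                cand = (q, tag, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist[frozenset((i, j))]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new = next_id
        next_id += 1
        for k in ids:
            if k in (i, j):
                continue
            dist[frozenset((new, k))] = 0.5 * (
                dist[frozenset((i, k))] + dist[frozenset((j, k))] - dij
            )
        ids = [k for k in ids if k not in (i, j)] + [new]
        nodes[new] = parent
        names[new] = min(names[i], names[j])
    i, j, k = ids
    dij = dist[frozenset((i, j))]
    dik = dist[frozenset((i, k))]
    djk = dist[frozenset((j, k))]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    order = sorted((i, j, k), key=lambda x: names[x])
    root = TreeNode(children=[nodes[x] for x in order])
    root.length = None
    return root


def to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> float:
    return tree_a.compare_rfd(tree_b)
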