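"""Orthologue detection: E-value threshold choice, reciprocal best hits,
and connected-component grouping.

Two proteins are called orthologues when each is the other's best hit
(smallest E-value) in the pairwise comparison of their proteomes AND both
directed E-values fall strictly below a threshold. The threshold is chosen
analytically: comparing n_o organisms of at most n_p proteins each performs
at most n_p^2 * n_o^2 protein-protein comparisons, so holding the expected
number of spurious matches to M requires

    E = M / (n_p^2 * n_o^2),

using the E-value as a proxy for the per-comparison spurious-match
probability P = 1 - exp(-E) (P ~= E for E < 0.01). Orthologous groups are
the connected components of the undirected graph whose edges are the
accepted reciprocal-best-hit pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .engine import HitTable


@dataclass(frozen=True)
class ThresholdSpec:
    """Analytically derived E-value threshold.

    M is the tolerated expected number of spurious matches over the whole
    experiment; n_p the size of the largest proteome compared (the caller may
    round it up conservatively); n_o the number of organisms.
    """

    M: float
    n_p: int
    n_o: int
    evalue: float
    power_of_ten: int

    def __float__(self) -> float:
        return self.evalue


def choose_evalue_threshold(M: float, n_p: int, n_o: int) -> ThresholdSpec:
    """E = M / (n_p^2 * n_o^2), with the nearest power of ten reported."""
    if M <= 0 or n_p <= 0 or n_o <= 0:
        raise ValueError("M, n_p and n_o must all be positive")
    evalue = M / (float(n_p) ** 2 * float(n_o) ** 2)
    return ThresholdSpec(M, n_p, n_o, evalue, round(math.log10(evalue)))


def spurious_match_probability(evalue: float) -> float:
    """P = 1 - exp(-E): probability of at least one chance match."""
    if evalue < 0:
        raise ValueError("E-value must be >= 0")
    return -math.expm1(-evalue)


def reciprocal_best_hits(hits_ab: HitTable, hits_ba: HitTable,
                         threshold: float) -> set[frozenset]:
    """Undirected RBH edges between two proteomes.

    Edge (P1, P2) exists iff P2 is P1's best hit, P1 is P2's best hit, and
    both E-values are strictly below ``threshold``.
    """
    best_ab = hits_ab.best_hits()
    best_ba = hits_ba.best_hits()
    edges: set[frozenset] = set()
    for q, hit in best_ab.items():
        back = best_ba.get(hit.subject_id)
        if back is None or back.subject_id != q:
            continue
        if hit.evalue < threshold and back.evalue < threshold:
            edges.add(frozenset((q, hit.subject_id)))
    return edges


def rbh_edges_all(tables: Mapping[tuple[str, str], HitTable],
                  threshold: float) -> dict[frozenset, set[frozenset]]:
    """RBH edge sets for every unordered isolate pair in an all-vs-all run."""
    out: dict[frozenset, set[frozenset]] = {}
    seen = set()
    for (a, b) in tables:
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        out[key] = reciprocal_best_hits(tables[(a, b)], tables[(b, a)], threshold)
    return out


@dataclass
class OrthologGroup:
    """A connected component of the RBH graph."""

    group_id: str
    members: frozenset
    isolates: frozenset

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        return len(self.isolates)


def ortholog_groups(edges: Iterable[frozenset | tuple], universe: Iterable[str],
                    isolate_of=None) -> list[OrthologGroup]:
    """Partition the protein universe into connected components.

    Singleton components are kept; group IDs are assigned in order of each
    component's smallest member ID, which makes the partition deterministic
    and invariant under input permutation.
    """
    universe = set(universe)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for edge in edges:
        u, v = tuple(edge)
        if u not in universe or v not in universe:
            raise ValueError(f"edge ({u}, {v}) references unknown protein")
        graph.add_edge(u, v)
    if isolate_of is None:
        from .io import protein_isolate_label as isolate_of
    components = sorted(nx.connected_components(graph), key=min)
    return [
        OrthologGroup(f"OG{i + 1:06d}", frozenset(comp),
                      frozenset(isolate_of(p) for p in comp))
        for i, comp in enumerate(components)
    ]


def threshold_sweep(hits_ab: HitTable, hits_ba: HitTable, n_queries: int,
                    exponents: Sequence[int] = tuple(range(0, -181, -1)),
                    ) -> dict[int, int]:
    """Unique-protein counts in proteome A over a grid of E-value thresholds.

    Hit tables are computed once (unthresholded) and filtered per step: for
    each threshold 10^e the count is the number of A proteins with no
    orthologue in B. Counts are monotone non-increasing as the threshold is
    made more permissive, since raising the threshold never removes an edge.
    """
    best_ab = hits_ab.best_hits()
    best_ba = hits_ba.best_hits()
    # max of the two directed E-values per reciprocal pair: the pair is an
    # edge at threshold t iff pair_e < t
    pair_e: list[float] = []
    for q, hit in best_ab.items():
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == q:
            pair_e.append(max(hit.evalue, back.evalue))
    counts: dict[int, int] = {}
    for e in exponents:
        t = 10.0 ** e
        matched = sum(1 for v in pair_e if v < t)
        counts[e] = n_queries - matched
    return counts
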