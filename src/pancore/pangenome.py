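"""Core proteomes, unique proteomes, singlets and pairwise similarity.

All core/unique/shared quantities are counted in orthologous GROUPS, not in
proteins: a group of 10 proteins spanning 8 isolates contributes 1 to the
core proteome of those isolates, not 10. Protein units appear only in the
average-unique-proteins measure and in per-isolate singlet counts.

Because reciprocal-best-hit edges depend only on the isolate pair they
connect, orthology over any isolate subset is the subgraph induced by that
subset's pairwise edges; :class:`PanGenome` exploits this to answer per-set
queries (genus cores, random-set cores, genus-restricted singlets) from one
all-vs-all run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io import protein_isolate_label
from .orthology import OrthologGroup, ortholog_groups, rbh_edges_all


def _isolates_of(group) -> frozenset:
    if isinstance(group, OrthologGroup):
        return group.isolates
    return frozenset(protein_isolate_label(p) for p in group)


def _members_of(group) -> frozenset:
    if isinstance(group, OrthologGroup):
        return group.members
    return frozenset(group)


def _check_universe(groups, isolate_set) -> None:
    seen = set()
    for g in groups:
        seen |= _isolates_of(g)
    missing = set(isolate_set) - seen
    if missing:
        raise ValueError(f"isolates absent from the protein universe: {sorted(missing)}")


def core_proteome(groups: Iterable, isolate_set: Iterable[str]) -> int:
    """Number of groups containing >=1 protein from EVERY isolate in the set."""
    isolate_set = set(isolate_set)
    if not isolate_set:
        raise ValueError("isolate set is empty")
    groups = list(groups)
    _check_universe(groups, isolate_set)
    return sum(1 for g in groups if isolate_set <= _isolates_of(g))


def unique_proteome(groups: Iterable, in_set: Iterable[str],
                    out_set: Iterable[str]) -> int:
    """Groups spanning every in-set isolate and touching no out-set isolate."""
    in_set, out_set = set(in_set), set(out_set)
    if in_set & out_set:
        raise ValueError("in-set and out-set overlap")
    if not in_set:
        raise ValueError("in-set is empty")
    count = 0
    for g in groups:
        isolates = _isolates_of(g)
        if in_set <= isolates and not (isolates & out_set):
            count += 1
    return count


def singlets(groups: Iterable) -> dict[str, int]:
    """Per-isolate counts of singleton components.

    The groups must come from an orthology run restricted to one genus; a
    singlet may still have orthologues outside that genus.
    """
    counts: dict[str, int] = {}
    for g in groups:
        members = _members_of(g)
        if len(members) == 1:
            (pid,) = members
            iso = next(iter(_isolates_of(g)))
            counts[iso] = counts.get(iso, 0) + 1
    return counts


def shared_proteins(groups: Iterable, isolate_a: str, isolate_b: str) -> int:
    """Groups containing proteins from both isolates (symmetric, group units)."""
    return sum(
        1 for g in groups
        if {isolate_a, isolate_b} <= _isolates_of(g)
    )


def average_unique_proteins(pair_edges: Iterable, pids_a: Sequence[str],
                            pids_b: Sequence[str]) -> float:
    """Mean of the two directed unmatched-protein counts for a pairwise run.

    A protein is "not in the other isolate" when it has no reciprocal-best-hit
    edge in the pairwise comparison; the result is in protein units and may be
    half-integral.
    """
    matched = set()
    for edge in pair_edges:
        matched |= set(edge)
    ua = sum(1 for p in pids_a if p not in matched)
    ub = sum(1 for p in pids_b if p not in matched)
    return (ua + ub) / 2.0


def lower_median(values: Sequence[int]) -> int:
    """Median with the lower of the two middle values for even counts."""
    if not values:
        raise ValueError("no values")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass
class PanGenomeSummary:
    """Per-group-set bookkeeping row (group units except where noted)."""

    label: str
    core_size: int
    unique_size: int
    singlets_per_isolate: dict[str, int]
    median_proteome_size: int

    @property
    def mean_singlets(self) -> float:
        v = self.singlets_per_isolate
        return sum(v.values()) / len(v) if v else 0.0


class PanGenome:
    """Per-set orthology queries over one all-vs-all RBH run.

    Parameters
    ----------
    proteins_by_isolate : mapping isolate label -> ordered protein IDs
    edges_by_pair : mapping frozenset({iso_a, iso_b}) -> set of RBH edges
    """

    def __init__(self, proteins_by_isolate: Mapping[str, Sequence[str]],
                 edges_by_pair: Mapping[frozenset, set]) -> None:
        self.proteins_by_isolate = {k: list(v) for k, v in proteins_by_isolate.items()}
        self.edges_by_pair = dict(edges_by_pair)
        self._group_cache: dict[frozenset, list[OrthologGroup]] = {}

    @staticmethod
    def from_hit_tables(pset, tables, threshold: float) -> "PanGenome":
        edges = rbh_edges_all(tables, float(threshold))
        return PanGenome({lab: pset.proteins_of(lab) for lab in pset.labels()}, edges)

    # -- plumbing ----------------------------------------------------------

    def isolates(self) -> list[str]:
        return list(self.proteins_by_isolate)

    def genera(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lab in self.proteins_by_isolate:
            out.setdefault(lab.split("|")[0], []).append(lab)
        return out

    def edges_within(self, isolates: Iterable[str]) -> set:
        isolates = list(isolates)
        edges: set = set()
        for i, a in enumerate(isolates):
            for b in isolates[i + 1:]:
                edges |= self.edges_by_pair.get(frozenset((a, b)), set())
        return edges

    def groups_for(self, isolates: Iterable[str]) -> list[OrthologGroup]:
        """Orthologous groups from the run restricted to these isolates only."""
        key = frozenset(isolates)
        if key not in self._group_cache:
            universe = [p for iso in sorted(key) for p in self.proteins_by_isolate[iso]]
            self._group_cache[key] = ortholog_groups(self.edges_within(key), universe)
        return self._group_cache[key]

    # -- the measures ------------------------------------------------------

    def core(self, isolates: Iterable[str]) -> int:
        isolates = set(isolates)
        return core_proteome(self.groups_for(isolates), isolates)

    def unique(self, in_set: Iterable[str], out_set: Iterable[str]) -> int:
        in_set, out_set = set(in_set), set(out_set)
        groups = self.groups_for(in_set | out_set)
        return unique_proteome(groups, in_set, out_set)

    def genus_unique(self, genus: str) -> int:
        """Groups in all isolates of ``genus`` and in no other isolate at all."""
        genera = self.genera()
        in_set = genera[genus]
        out_set = [iso for g, labs in genera.items() if g != genus for iso in labs]
        return self.unique(in_set, out_set)

    def genus_unique_pairwise(self, genus: str) -> int:
        """Genus-unique proteome via pairwise genus-vs-genus comparisons.

        Mirrors the memory-saving workaround of running orthology on one
        genus pair at a time: for each other genus B, find proteins of the
        focal genus lying in groups that span the genus and avoid B; proteins
        on every per-pair list form the unique proteome, counted as the
        genus-restricted groups they comprise. Must agree with
        :meth:`genus_unique` whenever no between-genus chaining occurs.
        """
        genera = self.genera()
        if genus not in genera:
            raise ValueError(f"unknown genus {genus}")
        others = [g for g in genera if g != genus]
        if not others:
            raise ValueError("need at least one other genus")
        in_set = set(genera[genus])
        survivors: set[str] | None = None
        for other in others:
            groups = self.groups_for(in_set | set(genera[other]))
            ok: set[str] = set()
            for g in groups:
                if in_set <= g.isolates and not (g.isolates - in_set):
                    ok |= set(g.members)
            survivors = ok if survivors is None else (survivors & ok)
        assert survivors is not None
        count = 0
        for g in self.groups_for(in_set):
            if in_set <= g.isolates and g.members <= survivors:
                count += 1
        return count

    def genus_singlets(self, genus: str) -> dict[str, int]:
        labs = self.genera()[genus]
        counts = {iso: 0 for iso in labs}
        counts.update(singlets(self.groups_for(labs)))
        return counts

    def shared(self, iso_a: str, iso_b: str) -> int:
        return shared_proteins(self.groups_for({iso_a, iso_b}), iso_a, iso_b)

    def avg_unique(self, iso_a: str, iso_b: str) -> float:
        edges = self.edges_by_pair.get(frozenset((iso_a, iso_b)), set())
        return average_unique_proteins(edges, self.proteins_by_isolate[iso_a],
                                       self.proteins_by_isolate[iso_b])

    def genus_summary_row(self, genus: str, with_unique: bool = True) -> PanGenomeSummary:
        labs = self.genera()[genus]
        sizes = [len(self.proteins_by_isolate[iso]) for iso in labs]
        unique = self.genus_unique(genus) if with_unique and len(self.genera()) > 1 else 0
        return PanGenomeSummary(
            label=genus,
            core_size=self.core(labs),
            unique_size=unique,
            singlets_per_isolate=self.genus_singlets(genus),
            median_proteome_size=lower_median(sizes),
        )


def genus_summary(summaries: Sequence[PanGenomeSummary]):
    """Cross-genus table plus least-squares fits against median proteome size.

    Returns ``(rows, fits)`` where ``rows`` is a list of per-genus dicts and
    ``fits`` maps panel name -> (slope, intercept, r_squared); fits are None
    with fewer than three genera.
    """
    if not summaries:
        raise ValueError("no genera")
    rows = [
        {
            "genus": s.label,
            "median_proteome_size": s.median_proteome_size,
            "core_size": s.core_size,
            "unique_size": s.unique_size,
            "mean_singlets": s.mean_singlets,
        }
        for s in summaries
    ]
    fits = None
    if len(summaries) >= 3:
        x = [s.median_proteome_size for s in summaries]
        fits = {}
        for panel, y in (
            ("core", [s.core_size for s in summaries]),
            ("unique", [s.unique_size for s in summaries]),
            ("mean_singlets", [s.mean_singlets for s in summaries]),
        ):
            res = stats.linregress(x, y)
            fits[panel] = (res.slope, res.intercept, res.rvalue ** 2)
    return rows, fits
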