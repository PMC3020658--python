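"""Core/unique/singlet accounting in group units, plus pair similarity."""

import pytest

from pancore.orthology import OrthologGroup
from pancore.pangenome import (
    PanGenomeSummary,
    average_unique_proteins,
    core_proteome,
    genus_summary,
    lower_median,
    shared_proteins,
    singlets,
    unique_proteome,
)
from oracles import ols_normal_equations


def make_group(gid, members_by_isolate):
    members = []
    isolates = []
    for iso, pids in members_by_isolate.items():
        isolates.append(iso)
        members.extend(pids)
    return OrthologGroup(gid, frozenset(members), frozenset(isolates))


class TestCoreProteome:
    def test_groups_counted_once_regardless_of_member_count(self):
        # 500 groups, each with 10 proteins spanning all 8 isolates: the core
        # size is 500 groups, not 500 * 10 = 5000 proteins
        isolates = [f"G|s|i{k}" for k in range(8)]
        groups = []
        for g in range(500):
            members = {iso: [f"{iso}|g{g}a"] for iso in isolates[:6]}
            for iso in isolates[6:]:
                members[iso] = [f"{iso}|g{g}a", f"{iso}|g{g}b"]
            groups.append(make_group(f"OG{g}", members))
        assert sum(gr.size for gr in groups) == 5000
        assert core_proteome(groups, isolates) == 500

    def test_single_isolate_set(self):
        groups = [
            make_group("a", {"G|s|i1": ["G|s|i1|p1"]}),
            make_group("b", {"G|s|i2": ["G|s|i2|p1"]}),
        ]
        assert core_proteome(groups, ["G|s|i1"]) == 1

    def test_monotone_non_increasing_as_isolates_added(self, small_world):
        pset, _, _, result = small_world
        pang = result.pangenome
        labs = pang.genera()["G1"] + pang.genera()["G2"]
        sizes = [pang.core(labs[:k]) for k in range(1, len(labs) + 1)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_recovers_planted_counts(self, small_world):
        _, _, truth, result = small_world
        pang = result.pangenome
        for genus, labs in pang.genera().items():
            assert pang.core(labs) == truth.expected_core(genus)

    def test_unknown_isolate_rejected(self):
        groups = [make_group("a", {"G|s|i1": ["G|s|i1|p1"]})]
        with pytest.raises(ValueError, match="absent from the protein universe"):
            core_proteome(groups, ["G|s|i1", "G|s|ghost"])


class TestUniqueProteome:
    def test_empty_out_set_equals_core(self):
        isolates = [f"G|s|i{k}" for k in range(3)]
        groups = [
            make_group("a", {iso: [f"{iso}|p1"] for iso in isolates}),
            make_group("b", {isolates[0]: [f"{isolates[0]}|p2"]}),
        ]
        assert unique_proteome(groups, isolates, []) == core_proteome(groups, isolates)

    def test_foreign_protein_excludes_group(self):
        members = {f"A|s|i{k}": [f"A|s|i{k}|p"] for k in range(3)}
        members["B|s|i1"] = ["B|s|i1|p"]
        group = make_group("g", members)
        assert unique_proteome([group], list(members)[:3], ["B|s|i1"]) == 0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            unique_proteome([], ["x"], ["x"])

    def test_recovers_planted_counts(self, small_world):
        _, _, truth, result = small_world
        pang = result.pangenome
        for genus in pang.genera():
            assert pang.genus_unique(genus) == truth.expected_unique(genus)

    def test_pairwise_equals_global(self, small_world):
        # the memory-saving genus-pair workaround must agree with the global
        # computation on a three-genus world
        _, _, _, result = small_world
        pang = result.pangenome
        for genus in pang.genera():
            assert pang.genus_unique_pairwise(genus) == pang.genus_unique(genus)

    def test_fully_shared_genus_has_no_unique_proteome(self):
        groups = [
            make_group(f"g{k}", {"A|s|i1": [f"A|s|i1|p{k}"],
                                 "A|s|i2": [f"A|s|i2|p{k}"],
                                 "B|s|i1": [f"B|s|i1|p{k}"]})
            for k in range(4)
        ]
        assert unique_proteome(groups, ["A|s|i1", "A|s|i2"], ["B|s|i1"]) == 0


class TestSinglets:
    def test_identical_isolates_have_no_singlets(self):
        isolates = ["G|s|i1", "G|s|i2"]
        groups = [make_group("g", {iso: [f"{iso}|p"] for iso in isolates})]
        assert singlets(groups) == {}

    def test_recovers_planted_counts(self, small_world):
        _, _, truth, result = small_world
        pang = result.pangenome
        for genus in pang.genera():
            assert pang.genus_singlets(genus) == truth.expected_singlets(genus)

    def test_single_isolate_genus_every_protein_is_a_singlet(self):
        groups = [
            make_group(f"g{k}", {"G|s|i1": [f"G|s|i1|p{k}"]}) for k in range(5)
        ]
        assert singlets(groups) == {"G|s|i1": 5}


class TestPairSimilarity:
    def test_shared_counts_groups_spanning_both(self):
        groups = [
            make_group("g1", {"A|s|a": ["A|s|a|p1"], "A|s|b": ["A|s|b|p1"]}),
            make_group("g2", {"A|s|a": ["A|s|a|p2"]}),
        ]
        assert shared_proteins(groups, "A|s|a", "A|s|b") == 1
        assert shared_proteins(groups, "A|s|b", "A|s|a") == 1

    def test_disjoint_isolates_share_nothing(self):
        groups = [make_group("g", {"A|s|a": ["A|s|a|p1"]}),
                  make_group("h", {"A|s|b": ["A|s|b|p1"]})]
        assert shared_proteins(groups, "A|s|a", "A|s|b") == 0

    def test_average_unique_hand_case(self):
        # |A\B| = 4, |B\A| = 2 -> 3
        pids_a = [f"a{i}" for i in range(6)]
        pids_b = [f"b{i}" for i in range(4)]
        edges = [frozenset(("a0", "b0")), frozenset(("a1", "b1"))]
        assert average_unique_proteins(edges, pids_a, pids_b) == 3.0

    def test_identical_proteomes_zero_average_unique(self):
        edges = [frozenset((f"a{i}", f"b{i}")) for i in range(3)]
        assert average_unique_proteins(edges, ["a0", "a1", "a2"],
                                       ["b0", "b1", "b2"]) == 0.0

    def test_pipeline_matches_direct_count(self, small_world):
        pset, _, _, result = small_world
        pang = result.pangenome
        a, b = pang.genera()["G1"][:2]
        edges = pang.edges_by_pair[frozenset((a, b))]
        matched_a = len({p for e in edges for p in e
                         if p in set(pset.proteins_of(a))})
        matched_b = len({p for e in edges for p in e
                         if p in set(pset.proteins_of(b))})
        expected = ((pset.proteome_size(a) - matched_a)
                    + (pset.proteome_size(b) - matched_b)) / 2
        assert pang.avg_unique(a, b) == expected


class TestGenusSummary:
    @staticmethod
    def summary(label, median, core, unique=0, singlets_mean=0.0):
        return PanGenomeSummary(label, core, unique,
                                {"i1": singlets_mean}, median)

    def test_exact_linearity_gives_unit_r_squared(self):
        rows = [self.summary(f"g{k}", m, core=m // 2) for k, m in
                enumerate([1000, 2000, 3000, 4000])]
        _, fits = genus_summary(rows)
        slope, _, r2 = fits["core"]
        assert slope == pytest.approx(0.5)
        assert r2 == pytest.approx(1.0)

    def test_single_genus_rows_only_no_fit(self):
        rows, fits = genus_summary([self.summary("g", 1000, 700)])
        assert len(rows) == 1 and fits is None

    def test_fit_matches_normal_equations(self):
        medians = [900, 1400, 2100, 3000]
        cores = [500, 820, 1010, 1900]
        rows = [self.summary(f"g{k}", m, c) for k, (m, c) in
                enumerate(zip(medians, cores))]
        _, fits = genus_summary(rows)
        slope, intercept, r2 = fits["core"]
        o_slope, o_intercept, o_r2 = ols_normal_equations(medians, cores)
        assert slope == pytest.approx(o_slope, rel=1e-10)
        assert intercept == pytest.approx(o_intercept, rel=1e-10)
        assert r2 == pytest.approx(o_r2, rel=1e-10)

    def test_lower_median_for_even_counts(self):
        assert lower_median([4, 1, 3, 2]) == 2
        assert lower_median([5, 1, 3]) == 3
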