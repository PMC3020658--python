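"""Distance metrics, UPGMA/NJ construction, Newick round-trips."""

import numpy as np
import pytest

from pancore.trees import (
    DistanceMatrix,
    avg_unique_distance,
    from_newick,
    marker_distance,
    neighbor_joining,
    robinson_foulds,
    snel_distance,
    to_newick,
    upgma,
)
from oracles import linkage_clades, tree_clades


class TestDistances:
    def test_snel_distance(self):
        assert snel_distance(1000, 1000) == 0.0
        assert snel_distance(0, 1000) == 1.0
        assert snel_distance(750, 1000) == pytest.approx(0.25)

    def test_snel_rejects_shared_exceeding_proteome(self):
        with pytest.raises(ValueError):
            snel_distance(1001, 1000)

    def test_marker_distance(self):
        assert marker_distance(100.0) == 0.0
        assert marker_distance(0.0) == 1.0
        assert marker_distance(99.50) == pytest.approx(0.005)
        with pytest.raises(ValueError):
            marker_distance(101.0)

    def test_avg_unique_distance_is_the_measure_itself(self):
        assert avg_unique_distance(0.0) == 0.0
        assert avg_unique_distance(3.0) == 3.0
        with pytest.raises(ValueError):
            avg_unique_distance(-1.0)


def random_distance_matrix(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.5, 4.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"t{i}" for i in range(n)], m)


class TestDistanceMatrix:
    def test_rejects_asymmetry_and_nan(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]))

    def test_tsv_round_trip(self):
        dm = random_distance_matrix(5, 0)
        back = DistanceMatrix.read_tsv(dm.to_tsv())
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.data, dm.data, atol=1e-6)


class TestUpgma:
    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        tree = upgma(dm)
        assert {t.name for t in tree.tips()} == {"A", "B"}
        assert all(t.length == pytest.approx(2.0) for t in tree.tips())

    def test_hand_executed_three_taxon_case(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]]))
        tree = upgma(dm)
        # ((A:1,B:1):2,C:3)
        (ab,) = [n for n in tree.children if n.children]
        (c,) = [n for n in tree.children if not n.children]
        assert c.name == "C" and c.length == pytest.approx(3.0)
        assert ab.length == pytest.approx(2.0)
        assert {t.name for t in ab.tips()} == {"A", "B"}
        assert all(t.length == pytest.approx(1.0) for t in ab.tips())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_average_linkage(self, seed):
        dm = random_distance_matrix(8, seed)
        mine = {(leaves, round(h, 9)) for leaves, h in tree_clades(upgma(dm))}
        scipy_clades = {(leaves, round(h, 9))
                        for leaves, h in linkage_clades(dm.labels, dm.data)}
        assert mine == scipy_clades

    def test_recovers_generating_ultrametric_tree(self):
        # ((A:1,B:1):2,(C:2,D:2):1) as an ultrametric distance matrix
        labels = ["A", "B", "C", "D"]
        d = {("A", "B"): 2.0, ("C", "D"): 4.0}
        m = np.full((4, 4), 6.0)
        np.fill_diagonal(m, 0.0)
        for (a, b), v in d.items():
            i, j = labels.index(a), labels.index(b)
            m[i, j] = m[j, i] = v
        tree = upgma(DistanceMatrix(labels, m))
        clades = {leaves for leaves, _ in tree_clades(tree)}
        assert frozenset({"A", "B"}) in clades
        assert frozenset({"C", "D"}) in clades
        heights = dict(tree_clades(tree))
        assert heights[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert heights[frozenset({"A", "B", "C", "D"})] == pytest.approx(3.0)

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))


def additive_matrix_from_tree():
    """Known 4-taxon unrooted tree: ((A:1,B:2):3,(C:4,D:5)) with internal 3."""
    labels = ["A", "B", "C", "D"]
    leg = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}
    internal = 3.0
    side = {"A": 0, "B": 0, "C": 1, "D": 1}
    m = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                m[i, j] = leg[x] + leg[y] + (internal if side[x] != side[y] else 0.0)
    return DistanceMatrix(labels, m), leg, internal


class TestNeighborJoining:
    def test_exact_recovery_on_additive_matrix(self):
        dm, leg, internal = additive_matrix_from_tree()
        tree = neighbor_joining(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {k: pytest.approx(v) for k, v in leg.items()}
        internal_nodes = [n for n in tree.traverse(include_self=False)
                          if n.children]
        assert len(internal_nodes) == 1
        assert internal_nodes[0].length == pytest.approx(internal)
        # the {A,B} | {C,D} split is present
        splits = {frozenset(t.name for t in n.tips()) for n in internal_nodes}
        assert splits == {frozenset({"A", "B"})} or splits == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_topology_matches_skbio_nj(self, seed):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        dm = random_distance_matrix(7, seed)
        mine = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.data, ids=dm.labels))
        assert robinson_foulds(mine, theirs) == 0.0

    def test_ultrametric_matrix_gives_upgma_topology(self):
        dm, *_ = additive_matrix_from_tree()
        # make it ultrametric instead: heights 1, 2, 3
        labels = ["A", "B", "C", "D"]
        m = np.full((4, 4), 6.0)
        np.fill_diagonal(m, 0.0)
        m[0, 1] = m[1, 0] = 2.0
        m[2, 3] = m[3, 2] = 4.0
        um = DistanceMatrix(labels, m)
        assert robinson_foulds(neighbor_joining(um), upgma(um)) == 0.0

    def test_star_tree_zero_internal_branches(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], m))
        for node in tree.traverse(include_self=False):
            if node.children:
                assert node.length == pytest.approx(0.0)

    def test_rejects_fewer_than_three_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestNewickAndCoupledTrees:
    def test_newick_round_trip_is_byte_stable(self):
        dm = random_distance_matrix(6, 4)
        text = to_newick(upgma(dm))
        again = to_newick(from_newick(text))
        assert text == again
        assert {t.name for t in from_newick(text).tips()} == set(dm.labels)

    def test_marker_and_shared_trees_agree_under_full_coupling(self):
        # with coupling 1 and deterministic marker substitution, the marker
        # tree and the gene-content (Snel) tree share their topology
        from pancore.experiments import regression_config
        from pancore.markers import percent_identity
        from pancore.pangenome import shared_proteins
        from pancore.simulate import simulate_pangenome

        _, marker, truth = simulate_pangenome(regression_config(2, 1.0))
        groups = truth.to_groups()
        pang = truth.to_pangenome()
        sizes = {iso: len(v) for iso, v in pang.proteins_by_isolate.items()}
        labels = sorted(marker)
        marker_dm = DistanceMatrix.from_pairs(
            labels, lambda a, b: marker_distance(percent_identity(marker[a],
                                                                  marker[b])))
        snel_dm = DistanceMatrix.from_pairs(
            labels, lambda a, b: snel_distance(shared_proteins(groups, a, b),
                                               min(sizes[a], sizes[b])))
        rf = robinson_foulds(upgma(marker_dm), upgma(snel_dm))
        assert rf == 0.0
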