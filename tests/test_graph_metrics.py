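"""Nodal/global tree metrics, occurrence tables and reference overlap."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plvtree.graph_metrics import (
    global_metrics,
    nodal_metrics,
    occurrence,
    overlap,
)
from plvtree.mst import TreeGraph, line_edges, random_tree_edges, star_edges


def star(n=14):
    return TreeGraph(n_nodes=n, edges=star_edges(n))


def line(n=14):
    return TreeGraph(n_nodes=n, edges=line_edges(n))


def brute_force_bc(tree: TreeGraph) -> np.ndarray:
    """Path-enumeration betweenness: for each r, count pairs whose unique
    path passes through r, over (N-1)(N-2)/2 pairs."""
    g = tree.to_networkx()
    n = tree.n_nodes
    counts = np.zeros(n)
    for p, q in itertools.combinations(range(n), 2):
        path = nx.shortest_path(g, p, q)
        for r in path[1:-1]:
            counts[r] += 1
    return counts / ((n - 1) * (n - 2) / 2)


class TestNodal:
    def test_star_closed_forms(self):
        nm = nodal_metrics(star())
        hub = int(np.argmax(nm.degree))
        assert nm.degree[hub] == 13
        assert nm.betweenness[hub] == 1.0  # central node of a star
        assert np.all(nm.betweenness[np.arange(14) != hub] == 0.0)  # leaves
        assert nm.eccentricity[hub] == 1
        assert np.all(nm.eccentricity[np.arange(14) != hub] == 2)

    def test_degree_sum_and_leaf_bc_zero(self, rng):
        for _ in range(30):
            tree = TreeGraph(n_nodes=10, edges=random_tree_edges(10, rng))
            nm = nodal_metrics(tree)
            assert nm.degree.sum() == 2 * 9
            assert np.all(nm.betweenness[nm.degree == 1] == 0.0)

    def test_bc_matches_path_enumeration_oracle(self, rng):
        """200 random 8-node trees against brute-force path counting."""
        for _ in range(200):
            tree = TreeGraph(n_nodes=8, edges=random_tree_edges(8, rng))
            nm = nodal_metrics(tree)
            assert np.allclose(nm.betweenness, brute_force_bc(tree), atol=1e-12)


class TestGlobal:
    def test_star_closed_forms(self):
        gm = global_metrics(star())
        assert gm.leaf_fraction == 1.0
        assert gm.tree_hierarchy == 0.5
        assert gm.diameter == pytest.approx(2 / 13)
        assert gm.kappa == pytest.approx(7.0)  # (13^2 + 13) / 26
        assert gm.eccentricity == 1.0  # max 2 - min 1
        assert gm.k_max == 13

    def test_line_closed_forms(self):
        gm = global_metrics(line())
        assert gm.leaf_fraction == pytest.approx(2 / 13)
        assert gm.diameter == 1.0
        assert gm.kappa == pytest.approx(50 / 26)
        assert gm.k_max == 2

    def test_leaf_fraction_rounding_worked_examples(self, rng):
        """Trees with 10 and 8 leaves on 14 nodes give L_f 0.77 and 0.62."""
        seen = set()
        for _ in range(2000):
            tree = TreeGraph(n_nodes=14, edges=random_tree_edges(14, rng))
            gm = global_metrics(tree)
            assert gm.leaf_count == round(gm.leaf_fraction * 13)
            if gm.leaf_count in (10, 8):
                seen.add((gm.leaf_count, round(gm.leaf_fraction, 2)))
            if len(seen) == 2:
                break
        assert seen == {(10, 0.77), (8, 0.62)}

    def test_th_half_iff_star_d_one_iff_line(self, rng):
        for _ in range(50):
            tree = TreeGraph(n_nodes=9, edges=random_tree_edges(9, rng))
            gm = global_metrics(tree)
            is_star = max(tree.degrees()) == 8
            is_line = max(tree.degrees()) == 2
            # star => T_H = 0.5 (the converse is false: e.g. L=6, BC_max=0.75
            # on 9 nodes also gives 0.5); D = 1 <=> path graph
            if is_star:
                assert gm.tree_hierarchy == 0.5
            assert (gm.diameter == 1.0) == is_line
            assert 2 / 8 <= gm.leaf_fraction <= 1.0
            assert 0.0 < gm.tree_hierarchy <= 1.0
            assert gm.kappa >= 2 - 2 / 9

    def test_ecc_variants(self):
        gm_range = global_metrics(line(), ecc_variant="range")
        gm_max = global_metrics(line(), ecc_variant="max")
        # line on 14: eccentricities run 7..13
        assert gm_range.eccentricity == 6.0
        assert gm_max.eccentricity == 13.0

    def test_relabeling_invariance(self, rng):
        tree = TreeGraph(n_nodes=10, edges=random_tree_edges(10, rng))
        perm = rng.permutation(10)
        relabeled = tree.relabel(perm)
        a, b = global_metrics(tree), global_metrics(relabeled)
        for name in ("leaf_fraction", "k_max", "bc_max", "eccentricity",
                     "kappa", "diameter", "tree_hierarchy"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_too_small_tree_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            global_metrics(TreeGraph(n_nodes=2, edges=((0, 1),)))


class TestOccurrence:
    def test_seven_of_nine_hub(self, rng):
        """A node that is a hub in 7 of 9 trees scores 77.8%."""
        trees = []
        for i in range(9):
            if i < 7:
                trees.append(star(6))  # node 0 is the hub
            else:
                trees.append(TreeGraph(n_nodes=6, edges=line_edges(6)))
        occ = occurrence(trees)
        assert occ.hub_occurrence[0] == pytest.approx(7 / 9)
        assert round(100 * occ.hub_occurrence[0], 1) == 77.8

    def test_identical_trees_degenerate_cohort(self):
        trees = [line(8) for _ in range(5)]
        occ = occurrence(trees)
        for a, b in trees[0].edges:
            assert occ.edge_occurrence[a, b] == 1.0
        assert occ.edge_occurrence.sum() == 2 * 7  # symmetric, only tree edges

    def test_counting_oracle(self, rng):
        trees = [TreeGraph(n_nodes=7, edges=random_tree_edges(7, rng))
                 for _ in range(11)]
        occ = occurrence(trees)
        total_hubs = sum(int(np.sum(t.degrees() > 1)) for t in trees)
        total_edges = sum(len(t.edges) for t in trees)
        assert occ.hub_occurrence.sum() * 11 == pytest.approx(total_hubs)
        assert occ.edge_occurrence.sum() / 2 * 11 == pytest.approx(total_edges)
        assert np.all(occ.hub_occurrence >= 0) and np.all(occ.hub_occurrence <= 1)

    def test_threshold_tagging(self):
        trees = [star(5), star(5), TreeGraph(n_nodes=5, edges=line_edges(5))]
        occ = occurrence(trees, threshold=0.5)
        assert (0, 1) in occ.frequent_edges  # in 2 of 3 trees (and in the line)


class TestOverlap:
    def test_self_overlap_full(self, rng):
        tree = TreeGraph(n_nodes=14, edges=random_tree_edges(14, rng))
        sim = overlap(tree, tree)
        assert sim.overlap_fraction == 1.0
        assert sim.overlap_percent == 100.0

    def test_three_shared_edges_is_23_percent(self, rng):
        """14-node trees sharing exactly 3 edges overlap 3/13 = 23.08%."""
        for _ in range(500):
            t1 = TreeGraph(n_nodes=14, edges=random_tree_edges(14, rng))
            t2 = TreeGraph(n_nodes=14, edges=random_tree_edges(14, rng))
            sim = overlap(t1, t2)
            assert sim.overlap_fraction == sim.shared_edges / 13
            if sim.shared_edges == 3:
                assert round(sim.overlap_percent, 2) == 23.08
                return
        pytest.fail("no pair with exactly 3 shared edges found")

    def test_star_vs_line_single_shared_edge(self):
        """Star hubbed at a line endpoint shares exactly the first line edge."""
        sim = overlap(star(14), line(14))
        assert sim.shared_edges == 1
        assert sim.overlap_fraction == pytest.approx(1 / 13)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node"):
            overlap(star(14), star(13))
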