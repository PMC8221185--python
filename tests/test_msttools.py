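"""Maximum spanning tree extraction and tree measures.

The Kruskal implementation is checked against two independent oracles:
exhaustive enumeration of all labelled spanning trees (via Prüfer
sequences) and networkx's maximum_spanning_tree; betweenness is checked
against networkx's Brandes implementation.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from dynmst import SpanningTree, binarize, max_spanning_tree, mst_measures

from conftest import path_tree, star_tree


def all_spanning_tree_weights(adj):
    """Total weights of every labelled spanning tree, by Prüfer decoding."""
    n = adj.shape[0]
    weights = []
    for seq in itertools.product(range(n), repeat=n - 2):
        # decode the Prüfer sequence into an edge list
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        total = 0.0
        seq = list(seq)
        ptr = 0
        leaf = -1
        for x in seq:
            if leaf < 0:
                while degree[ptr] != 1:
                    ptr += 1
                leaf = ptr
            total += adj[leaf, x]
            degree[x] -= 1
            degree[leaf] -= 1
            if degree[x] == 1 and x < ptr:
                leaf = x
            else:
                leaf = -1
        u = [i for i in range(n) if degree[i] == 1]
        total += adj[u[0], u[1]]
        weights.append(total)
    return np.asarray(weights)


class TestMaxSpanningTree:
    def test_triangle_drops_weakest_edge(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 0.9
        adj[1, 2] = adj[2, 1] = 0.8
        adj[0, 2] = adj[2, 0] = 0.1
        tree = max_spanning_tree(adj)
        assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2)]
        assert tree.total_weight == pytest.approx(1.7)

    def test_dominant_hub_yields_star(self):
        n = 6
        adj = np.full((n, n), 0.1)
        adj[0, :] = adj[:, 0] = 0.9
        np.fill_diagonal(adj, 0.0)
        tree = max_spanning_tree(adj)
        deg = tree.degrees()
        assert deg[0] == n - 1
        assert all(d == 1 for d in deg[1:])

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n, rng):
        for _ in range(25):
            w = rng.random((n, n))
            adj = np.triu(w, 1) + np.triu(w, 1).T
            tree = max_spanning_tree(adj)
            assert tree.total_weight == pytest.approx(
                all_spanning_tree_weights(adj).max())

    def test_matches_networkx(self, rng):
        for _ in range(20):
            n = 8
            w = rng.random((n, n))
            adj = np.triu(w, 1) + np.triu(w, 1).T
            g = nx.from_numpy_array(adj)
            expected = nx.maximum_spanning_tree(g).size(weight="weight")
            assert max_spanning_tree(adj).total_weight == pytest.approx(expected)

    def test_deterministic_under_ties(self):
        adj = np.ones((5, 5)) - np.eye(5)
        e1 = max_spanning_tree(adj).edges
        e2 = max_spanning_tree(adj).edges
        assert e1 == e2
        # lexicographic tie-break picks node-0 edges first
        assert all(i == 0 for i, _, _ in e1)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            max_spanning_tree(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            max_spanning_tree(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            max_spanning_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestSpanningTreeInvariants:
    def test_rejects_cycle_and_wrong_count(self):
        with pytest.raises(ValueError):
            SpanningTree(n_nodes=3, edges=[(0, 1, 1.0)])
        with pytest.raises(ValueError):
            SpanningTree(n_nodes=3,
                         edges=[(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])

    def test_degree_sum_and_leaf_floor(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            w = rng.random((n, n))
            adj = np.triu(w, 1) + np.triu(w, 1).T
            tree = max_spanning_tree(adj)
            deg = tree.degrees()
            assert deg.sum() == 2 * (n - 1)
            assert np.sum(deg == 1) >= 2


class TestMeasures:
    def test_star_n5_normalized_values(self):
        m = mst_measures(star_tree(5))
        assert m.leaf_fraction == pytest.approx(1.0)
        assert m.max_degree == pytest.approx(1.0)
        assert m.diameter == pytest.approx(0.5)
        assert m.max_bc == pytest.approx(1.0)
        assert m.tree_hierarchy == pytest.approx(0.5)

    def test_path_n5_normalized_values(self):
        m = mst_measures(path_tree(5))
        assert m.leaf_fraction == pytest.approx(0.5)
        assert m.diameter == pytest.approx(1.0)
        assert m.max_bc == pytest.approx(2 / 3)
        assert m.tree_hierarchy == pytest.approx(0.375)

    @pytest.mark.parametrize("n", [5, 10, 63])
    def test_raw_extreme_structures(self, n):
        line = mst_measures(path_tree(n))
        assert line.raw_max_degree == 2
        assert line.raw_leaf_count == 2
        assert line.raw_diameter == n - 1
        star = mst_measures(star_tree(n))
        assert star.raw_max_degree == n - 1
        assert star.raw_leaf_count == n - 1
        assert star.raw_diameter == 2

    def test_star63_brackets_reported_diameter_scale(self):
        # 63-node extremes: star normalized diameter 2/62, line 1.0;
        # observed cortical backbones (~0.09-0.11) must lie inside.
        star = mst_measures(star_tree(63))
        line = mst_measures(path_tree(63))
        assert star.diameter < 0.09 < 0.11 < line.diameter

    def test_betweenness_matches_networkx(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            w = rng.random((n, n))
            adj = np.triu(w, 1) + np.triu(w, 1).T
            tree = max_spanning_tree(adj)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from([(i, j) for i, j, _ in tree.edges])
            expected = nx.betweenness_centrality(g, normalized=True)
            got = mst_measures(tree).node_bc
            for v in range(n):
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_eccentricity_matches_networkx(self, rng):
        n = 9
        w = rng.random((n, n))
        adj = np.triu(w, 1) + np.triu(w, 1).T
        tree = max_spanning_tree(adj)
        g = nx.Graph([(i, j) for i, j, _ in tree.edges])
        expected = nx.eccentricity(g)
        got = mst_measures(tree).eccentricity * (n - 1)
        for v in range(n):
            assert got[v] == pytest.approx(expected[v])

    def test_path_to_star_morph_is_monotone(self):
        # re-attaching the path's far end to the center one leaf at a time
        # must raise leaf fraction and max degree and shrink the diameter
        n = 9
        center = 0
        prev = None
        for k in range(n - 2):
            edges = [(i, i + 1, 1.0) for i in range(n - 1 - k)]
            edges += [(center, j, 1.0) for j in range(n - k, n)]
            m = mst_measures(SpanningTree(n_nodes=n, edges=edges))
            if prev is not None:
                assert m.leaf_fraction >= prev.leaf_fraction
                assert m.max_degree >= prev.max_degree
                assert m.diameter <= prev.diameter
            prev = m


class TestBinarize:
    def test_topology_preserved_weights_unit(self):
        tree = path_tree(6, weight=0.7)
        flat = binarize(tree)
        assert [(i, j) for i, j, _ in flat.edges] == \
            [(i, j) for i, j, _ in tree.edges]
        assert all(w == 1.0 for _, _, w in flat.edges)

    def test_topological_measures_invariant(self, rng):
        n = 10
        w = rng.random((n, n))
        adj = np.triu(w, 1) + np.triu(w, 1).T
        tree = max_spanning_tree(adj)
        a, b = mst_measures(tree), mst_measures(binarize(tree))
        for attr in ("diameter", "leaf_fraction", "max_bc", "max_degree",
                     "tree_hierarchy"):
            assert getattr(a, attr) == getattr(b, attr)
        np.testing.assert_array_equal(a.node_bc, b.node_bc)

    def test_mean_edge_pli_from_weights(self):
        tree = SpanningTree(n_nodes=3, edges=[(0, 1, 0.9), (1, 2, 0.8)])
        assert mst_measures(tree).mst_pli == pytest.approx(0.85)
        assert mst_measures(binarize(tree)).mst_pli == pytest.approx(1.0)
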