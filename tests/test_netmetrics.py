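import itertools

import numpy as np
import pytest

from resectnet.netmetrics import (CentralityTable, MSTGraph, betweenness,
                                  build_cost_graph, centrality_delta,
                                  centrality_from_matrices, closeness,
                                  eigenvector, global_centrality,
                                  minimum_spanning_tree, tree_centralities)


def _graph(values):
    return build_cost_graph(np.asarray(values, dtype=float))


def _star(n=5, cost=1.0, weight=1.0):
    """Hub 0 connected to leaves 1..n-1."""
    return MSTGraph(n_nodes=n, edges=[(0, j, cost, weight) for j in range(1, n)])


def _path3(cost=1.0, weight=1.0):
    return MSTGraph(n_nodes=3, edges=[(0, 1, cost, weight), (1, 2, cost, weight)])


def spanning_tree_min_cost(costs):
    """Brute-force minimum over all spanning trees via Pruefer sequences."""
    n = costs.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        edges = _pruefer_to_edges(seq, n)
        best = min(best, sum(costs[i, j] for i, j in edges))
    return best


def _pruefer_to_edges(seq, n):
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        leaf = min(i for i in range(n) if degree[i] == 1)
        edges.append((leaf, v))
        degree[leaf] -= 1
        degree[v] -= 1
    u, w = [i for i in range(n) if degree[i] == 1]
    edges.append((u, w))
    return edges


class TestCostGraph:
    def test_costs_are_reciprocals(self):
        g = _graph([[0, 0.5, 0.25], [0.5, 0, 0.1], [0.25, 0.1, 0]])
        assert g.costs[0, 1] == 2.0
        assert g.costs[0, 2] == 4.0
        assert g.costs[1, 2] == 10.0

    def test_zero_aec_floored_to_finite_cost(self):
        g = _graph([[0, 0.0], [0.0, 0]])
        assert np.isfinite(g.costs[0, 1]) and g.costs[0, 1] == 1e12

    def test_asymmetric_or_negative_rejected(self):
        with pytest.raises(ValueError):
            _graph([[0, 0.5], [0.4, 0]])
        with pytest.raises(ValueError):
            _graph([[0, -0.5], [-0.5, 0]])


class TestMST:
    def test_two_nodes_single_edge(self):
        t = minimum_spanning_tree(_graph([[0, 0.5], [0.5, 0]]))
        assert t.edges == [(0, 1, 2.0, 0.5)]

    def test_three_node_example_by_enumeration(self):
        # costs {2, 4, 10}: the three spanning trees cost 6, 12, 14
        t = minimum_spanning_tree(_graph([[0, .5, .25], [.5, 0, .1], [.25, .1, 0]]))
        assert [(i, j) for i, j, *_ in t.edges] == [(0, 1), (0, 2)]
        assert t.total_cost == 6.0

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            n = 6
            aec = rng.uniform(0.05, 1.0, size=(n, n))
            aec = 0.5 * (aec + aec.T)
            np.fill_diagonal(aec, 0.0)
            g = _graph(aec)
            t = minimum_spanning_tree(g)
            assert len(t.edges) == n - 1
            assert t.total_cost == pytest.approx(spanning_tree_min_cost(g.costs))

    def test_deterministic_tie_breaking(self):
        aec = np.full((4, 4), 0.5)
        np.fill_diagonal(aec, 0.0)
        t = minimum_spanning_tree(_graph(aec))
        assert [(i, j) for i, j, *_ in t.edges] == [(0, 1), (0, 2), (0, 3)]


class TestBetweenness:
    def test_star_hub_counts_all_pairs(self):
        bc = betweenness(_star(5))
        assert bc[0] == 6.0  # C(4, 2)
        np.testing.assert_array_equal(bc[1:], 0.0)

    def test_path_middle_node(self):
        np.testing.assert_array_equal(betweenness(_path3()), [0.0, 1.0, 0.0])

    def test_sum_identity_against_path_enumeration(self, rng):
        """Sum of betweenness = sum over pairs of (path length - 1)."""
        import networkx as nx
        aec = rng.uniform(0.1, 1.0, size=(7, 7))
        aec = 0.5 * (aec + aec.T)
        np.fill_diagonal(aec, 0.0)
        t = minimum_spanning_tree(_graph(aec))
        g = t.to_networkx()
        total = sum(len(nx.shortest_path(g, i, j)) - 2
                    for i in range(7) for j in range(i + 1, 7))
        assert betweenness(t).sum() == pytest.approx(total)


class TestCloseness:
    def test_unit_star_closed_form(self):
        cc = closeness(_star(5))
        assert cc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(cc[1:], 4.0 / 7.0)

    def test_doubling_costs_halves_closeness(self):
        t1, t2 = _star(6, cost=1.0), _star(6, cost=2.0)
        np.testing.assert_allclose(closeness(t2), closeness(t1) / 2)

    def test_two_node_tree(self):
        t = MSTGraph(n_nodes=2, edges=[(0, 1, 1.0, 1.0)])
        np.testing.assert_allclose(closeness(t), 1.0)


class TestEigenvector:
    def test_star_hub_leaf_ratio_sqrt_n_minus_1(self):
        ec = eigenvector(_star(5))
        assert ec[0] / ec[1] == pytest.approx(2.0, abs=1e-8)

    def test_path3_middle_ratio_sqrt2(self):
        ec = eigenvector(_path3())
        assert ec[1] / ec[0] == pytest.approx(np.sqrt(2), abs=1e-8)

    def test_nonnegative_and_nontrivial(self, rng):
        aec = rng.uniform(0.1, 1.0, size=(8, 8))
        aec = 0.5 * (aec + aec.T)
        np.fill_diagonal(aec, 0.0)
        ec = eigenvector(minimum_spanning_tree(_graph(aec)))
        assert (ec >= 0).all() and ec.any()

    def test_matches_dense_eigendecomposition(self, rng):
        aec = rng.uniform(0.1, 1.0, size=(10, 10))
        aec = 0.5 * (aec + aec.T)
        np.fill_diagonal(aec, 0.0)
        t = minimum_spanning_tree(_graph(aec))
        a = t.weight_adjacency()
        w, v = np.linalg.eigh(a)
        np.testing.assert_allclose(eigenvector(t), np.abs(v[:, -1]), atol=1e-6)


class TestGlobalCentrality:
    def test_star_composition_hub_is_one(self):
        table = global_centrality([tree_centralities(_star(5))],
                                  [f"r{i}" for i in range(5)])
        assert table.global_centrality[0] == pytest.approx(1.0)
        assert table.betweenness.max() == 1.0
        assert table.closeness.max() == 1.0
        assert table.eigenvector.max() == 1.0

    def test_normalized_max_is_exactly_one_per_measure(self, rng):
        mats = []
        for _ in range(4):
            m = rng.uniform(0.05, 1.0, size=(6, 6))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 0.0)
            mats.append(m)
        table = centrality_from_matrices(mats, [f"r{i}" for i in range(6)])
        for vals in (table.betweenness, table.closeness, table.eigenvector):
            assert vals.max() == pytest.approx(1.0)
            assert (vals >= 0).all() and (vals <= 1.0 + 1e-12).all()

    def test_zero_betweenness_dropped_from_composite(self):
        t = MSTGraph(n_nodes=2, edges=[(0, 1, 1.0, 1.0)])
        with pytest.warns(UserWarning):
            table = global_centrality([tree_centralities(t)], ["a", "b"])
        # both nodes symmetric: closeness and eigenvector normalized to 1
        np.testing.assert_allclose(table.global_centrality, 1.0)

    def test_permutation_equivariance(self, rng):
        m = rng.uniform(0.05, 1.0, size=(7, 7))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        perm = rng.permutation(7)
        names = [f"r{i}" for i in range(7)]
        t1 = centrality_from_matrices([m], names)
        t2 = centrality_from_matrices([m[np.ix_(perm, perm)]],
                                      [names[i] for i in perm])
        np.testing.assert_allclose(t2.global_centrality,
                                   t1.global_centrality[perm], atol=1e-9)

    def test_mst_edge_monotonicity(self, rng):
        """Raising the AEC of an edge already in the MST keeps it there."""
        m = rng.uniform(0.05, 0.9, size=(6, 6))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        t = minimum_spanning_tree(_graph(m))
        i, j, *_ = t.edges[2]
        m2 = m.copy()
        m2[i, j] = m2[j, i] = min(0.99, m[i, j] * 1.5)
        t2 = minimum_spanning_tree(_graph(m2))
        assert any(e[:2] == (min(i, j), max(i, j)) for e in t2.edges)

    def test_virtual_hub_resection_raises_remaining_centrality(self):
        """Removing a planted hub node lifts the mean normalized centrality
        of the remaining nodes (the qualitative successful-surgery signature)."""
        from resectnet.synth import planted_correlation
        c = planted_correlation(12, 0.15, 0, 0.7)
        aec = np.clip(c - np.eye(12), 0.0, None)
        with_hub = centrality_from_matrices([aec], [f"r{i}" for i in range(12)])
        without = centrality_from_matrices([aec[1:, 1:]],
                                           [f"r{i}" for i in range(1, 12)])
        assert (without.global_centrality.mean()
                > with_hub.global_centrality[1:].mean())


class TestCentralityDelta:
    def _table(self, vals, names=None):
        vals = np.asarray(vals, dtype=float)
        names = names or [f"r{i}" for i in range(len(vals))]
        return CentralityTable(roi_names=names, betweenness=vals,
                               closeness=vals, eigenvector=vals,
                               global_centrality=vals)

    def test_identical_tables_give_zero(self):
        t = self._table([0.2, 0.5, 1.0])
        assert (centrality_delta(t, t) == 0).all()

    def test_elementwise_difference(self):
        pre = self._table([0.4, 1.0])
        post = self._table([0.7, 1.0])
        d = centrality_delta(pre, post)
        assert d["r0"] == pytest.approx(0.3)

    def test_mismatched_rois_restricted_to_intersection(self):
        pre = self._table([0.4, 0.6], ["a", "b"])
        post = self._table([0.5, 0.2], ["b", "c"])
        d = centrality_delta(pre, post)
        assert list(d.index) == ["b"] and d["b"] == pytest.approx(-0.1)

    def test_bounded_in_unit_interval(self, rng):
        pre = self._table(rng.uniform(0, 1, 10))
        post = self._table(rng.uniform(0, 1, 10))
        d = centrality_delta(pre, post)
        assert ((d >= -1) & (d <= 1)).all()
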