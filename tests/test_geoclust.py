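"""Spatial clustering: distances, adjacency, spanning tree, tree pruning."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from kroncox import geoclust
from oracles import brute_silhouette, exhaustive_spanning_trees


class TestGreatCircle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((34.0, -118.0), (34.0, -118.0), 0.0),
            ((0.0, 0.0), (0.0, 180.0), np.pi * 6371.0088),
            ((0.0, 0.0), (0.0, 90.0), np.pi * 6371.0088 / 2),
        ],
    )
    def test_reference_distances(self, a, b, expected):
        assert geoclust.great_circle_distance(a, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_range_check(self, rng):
        pts = rng.uniform([-80, -170], [80, 170], size=(20, 2))
        for a, b in itertools.combinations(pts, 2):
            d1 = geoclust.great_circle_distance(a, b)
            assert d1 == pytest.approx(geoclust.great_circle_distance(b, a))
            assert d1 >= 0
        with pytest.raises(ValueError):
            geoclust.great_circle_distance((91.0, 0.0), (0.0, 0.0))


class TestAdjacency:
    def test_threshold_chain(self):
        # 3 collinear points ~10 km apart; 15 km threshold forces a chain
        units = [
            geoclust.SpatialUnit(f"u{i}", (34.0 + 0.09 * i, -118.0), 1.0, np.array([float(i)]))
            for i in range(3)
        ]
        g = geoclust.build_adjacency(units, "distance_threshold", d_km=15.0)
        assert g.adjacency.sum() == 4  # two undirected edges
        assert g.adjacency[0, 2] == 0

    def test_identical_attributes_zero_weights(self):
        units = [
            geoclust.SpatialUnit(f"u{i}", (34.0 + 0.05 * i, -118.0), 1.0, np.array([2.0, 3.0]))
            for i in range(3)
        ]
        g = geoclust.build_adjacency(units, "distance_threshold", d_km=50.0)
        assert all(w == 0.0 for w in g.edge_weights.values())

    def test_knn_matches_bruteforce_neighbors(self, rng):
        units = [
            geoclust.SpatialUnit(
                f"u{i}",
                tuple(rng.uniform([33, -119], [35, -117])),
                1.0,
                rng.standard_normal(2),
            )
            for i in range(5)
        ]
        g = geoclust.build_adjacency(units, "knn", k=2)
        D = geoclust.pairwise_great_circle(units)
        expected = np.zeros((5, 5), dtype=int)
        for i in range(5):
            nn = np.argsort([D[i, j] if j != i else np.inf for j in range(5)])[:2]
            expected[i, nn] = 1
        expected = np.maximum(expected, expected.T)
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_disconnected_raises_with_components(self):
        units = [
            geoclust.SpatialUnit("a", (34.0, -118.0), 1.0, np.zeros(1)),
            geoclust.SpatialUnit("b", (34.05, -118.0), 1.0, np.zeros(1)),
            geoclust.SpatialUnit("c", (44.0, -100.0), 1.0, np.zeros(1)),
            geoclust.SpatialUnit("d", (44.05, -100.0), 1.0, np.zeros(1)),
        ]
        with pytest.raises(geoclust.DisconnectedGraphError) as ei:
            geoclust.build_adjacency(units, "distance_threshold", d_km=50.0)
        assert len(ei.value.components) == 2

    def test_knn_k_too_large(self, square_units):
        with pytest.raises(ValueError, match="k=4"):
            geoclust.build_adjacency(square_units, "knn", k=4)


class TestMST:
    def _graph(self, n, edges):
        units = [
            geoclust.SpatialUnit(f"u{i}", (34.0 + 0.01 * i, -118.0), 1.0, np.zeros(1))
            for i in range(n)
        ]
        A = np.zeros((n, n), dtype=int)
        w = {}
        for i, j, wt in edges:
            A[i, j] = A[j, i] = 1
            w[(min(i, j), max(i, j))] = wt
        return geoclust.AdjacencyGraph(units, A, w)

    def test_two_nodes(self):
        g = self._graph(2, [(0, 1, 3.0)])
        tree = geoclust.minimum_spanning_tree(g)
        assert tree.edges == [(0, 1, 3.0)]

    def test_matches_exhaustive_minimum(self, rng):
        for _ in range(10):
            edges = [
                (i, j, float(rng.uniform(0.1, 10)))
                for i, j in itertools.combinations(range(4), 2)
            ]
            g = self._graph(4, edges)
            tree = geoclust.minimum_spanning_tree(g)
            best = min(
                sum(edges[ei][2] for ei in combo)
                for combo in exhaustive_spanning_trees(4, edges)
            )
            assert tree.total_weight() == pytest.approx(best)

    def test_deterministic_under_ties(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)]
        g = self._graph(5, edges)
        t1 = geoclust.minimum_spanning_tree(g)
        t2 = geoclust.minimum_spanning_tree(g)
        assert t1.edges == t2.edges

    def test_beats_random_spanning_trees(self, rng):
        # random graphs with <= 12 nodes: MST weight <= 100 random trees
        from conftest import random_connected_graph

        for _ in range(5):
            n = int(rng.integers(5, 13))
            A = random_connected_graph(rng, n)
            units = [
                geoclust.SpatialUnit(f"u{i}", (34 + 0.01 * i, -118.0), 1.0, np.zeros(1))
                for i in range(n)
            ]
            w = {
                (i, j): float(rng.uniform(0.1, 5))
                for i, j in zip(*np.nonzero(np.triu(A, 1)))
            }
            g = geoclust.AdjacencyGraph(units, A.astype(int), w)
            tree = geoclust.minimum_spanning_tree(g)
            edges = [(i, j, w[(i, j)]) for (i, j) in w]
            for _ in range(100):
                # random spanning tree: random-weight MST over the same graph
                wr = {e: float(rng.random()) for e in w}
                gr = geoclust.AdjacencyGraph(units, A.astype(int), wr)
                tr = geoclust.minimum_spanning_tree(gr)
                total = sum(w[(i, j)] for i, j, _ in tr.edges)
                assert tree.total_weight() <= total + 1e-12


class TestSSD:
    def test_hand_values(self):
        attrs = np.array([[0.0], [2.0]])
        assert geoclust.ssd([0], attrs) == 0.0
        assert geoclust.ssd([0, 1], attrs) == pytest.approx(2.0)

    def test_variance_identity(self, rng):
        attrs = rng.standard_normal((5, 3))
        expected = 4 * attrs.var(axis=0, ddof=1).sum()
        assert geoclust.ssd(range(5), attrs) == pytest.approx(expected)


class TestSkater:
    def test_single_cluster_is_total_ssd(self, square_units):
        g = geoclust.build_adjacency(square_units, "distance_threshold", d_km=30.0)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = geoclust.standardize_attributes(square_units)
        part = geoclust.skater(tree, 1, attrs)
        assert part.n_clusters == 1
        assert part.objective == pytest.approx(geoclust.ssd(range(4), attrs))

    def test_chain_gap_split(self):
        units = [
            geoclust.SpatialUnit(f"u{i}", (34.0 + 0.05 * i, -118.0), 1.0, np.array([v]))
            for i, v in enumerate([0.0, 0.0, 10.0, 10.0])
        ]
        g = geoclust.build_adjacency(units, "distance_threshold", d_km=10.0)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = np.array([[0.0], [0.0], [10.0], [10.0]])
        part = geoclust.skater(tree, 2, attrs)
        assert part.objective == pytest.approx(0.0)
        assert part.assignment[0] == part.assignment[1]
        assert part.assignment[2] == part.assignment[3]
        assert part.assignment[0] != part.assignment[2]

    def test_first_split_matches_exhaustive(self, rng):
        # on random trees, the first removed edge maximizes the SSD drop
        for trial in range(10):
            n = int(rng.integers(4, 9))
            units = [
                geoclust.SpatialUnit(f"u{i}", (34 + 0.02 * i, -118.0), 1.0, rng.standard_normal(2))
                for i in range(n)
            ]
            g = geoclust.connected_knn_adjacency(units, k=2)
            tree = geoclust.minimum_spanning_tree(g)
            attrs = geoclust.standardize_attributes(units)
            part = geoclust.skater(tree, 2, attrs)
            best_q = np.inf
            for eid in range(len(tree.edges)):
                from kroncox.geoclust import _split_by_edge

                a, b = _split_by_edge(tree.edges, set(tree.nodes), eid)
                q = geoclust.ssd(sorted(a), attrs) + geoclust.ssd(sorted(b), attrs)
                best_q = min(best_q, q)
            assert part.objective == pytest.approx(best_q)

    def test_objective_nonincreasing_and_connected(self, rng):
        units = [
            geoclust.SpatialUnit(f"u{i}", (34 + 0.02 * i, -118.0 + 0.01 * (i % 3)), 1.0,
                                 rng.standard_normal(2))
            for i in range(12)
        ]
        g = geoclust.connected_knn_adjacency(units, k=3)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = geoclust.standardize_attributes(units)
        prev = geoclust.ssd(range(12), attrs)
        nb = tree.neighbors()
        for C in range(2, 7):
            part = geoclust.skater(tree, C, attrs)
            assert part.objective <= prev + 1e-12
            prev = part.objective
            # every cluster induces a connected subtree (checked by traversal)
            for c in range(part.n_clusters):
                members = set(part.members(c).tolist())
                start = next(iter(members))
                seen = {start}
                stack = [start]
                while stack:
                    v = stack.pop()
                    for u in nb[v]:
                        if u in members and u not in seen:
                            seen.add(u)
                            stack.append(u)
                assert seen == members

    def test_population_constraint_respected(self, rng):
        units = [
            geoclust.SpatialUnit(f"u{i}", (34 + 0.02 * i, -118.0), float(10 + i), rng.standard_normal(1))
            for i in range(8)
        ]
        g = geoclust.connected_knn_adjacency(units, k=2)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = geoclust.standardize_attributes(units)
        pops = np.array([u.population for u in units])
        part = geoclust.skater(tree, 3, attrs, ("min_population", 25.0), pops)
        for c in range(part.n_clusters):
            assert pops[part.members(c)].sum() >= 25.0

    def test_infeasible_constraint_stops_early(self, square_units, rng):
        g = geoclust.build_adjacency(square_units, "distance_threshold", d_km=30.0)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = geoclust.standardize_attributes(square_units)
        pops = np.array([u.population for u in square_units])
        with pytest.warns(RuntimeWarning, match="no feasible split"):
            part = geoclust.skater(tree, 4, attrs, ("min_population", 300.0), pops)
        assert part.n_clusters < 4

    def test_too_many_clusters_raises(self, square_units):
        g = geoclust.build_adjacency(square_units, "distance_threshold", d_km=30.0)
        tree = geoclust.minimum_spanning_tree(g)
        attrs = geoclust.standardize_attributes(square_units)
        with pytest.raises(ValueError):
            geoclust.skater(tree, 5, attrs)


class TestSilhouette:
    def test_well_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(10, 0.05, (10, 2))])
        part = geoclust.Partition(np.repeat([0, 1], 10), 2)
        widths, mean_w = geoclust.silhouette_widths(part, X)
        assert mean_w > 0.9

    def test_degenerate_identical_points(self):
        X = np.ones((6, 2))
        part = geoclust.Partition(np.repeat([0, 1], 3), 2)
        widths, mean_w = geoclust.silhouette_widths(part, X)
        assert np.all(widths == 0.0)

    def test_matches_bruteforce_and_sklearn(self, rng):
        X = rng.standard_normal((10, 3))
        labels = rng.integers(0, 3, size=10)
        while len(set(labels.tolist())) < 3:
            labels = rng.integers(0, 3, size=10)
        part = geoclust.Partition(labels, 3)
        widths, _ = geoclust.silhouette_widths(part, X)
        np.testing.assert_allclose(widths, brute_silhouette(X, labels), atol=1e-12)
        np.testing.assert_allclose(
            widths, silhouette_samples(X, labels), atol=1e-10
        )

    def test_singleton_cluster_convention(self, rng):
        X = rng.standard_normal((5, 2))
        part = geoclust.Partition(np.array([0, 0, 0, 0, 1]), 2)
        widths, _ = geoclust.silhouette_widths(part, X)
        assert widths[4] == 0.0


def test_units_csv_roundtrip(tmp_path, square_units):
    from kroncox.simulate import units_to_frame

    path = tmp_path / "units.csv"
    units_to_frame(square_units).to_csv(path, index=False)
    loaded = geoclust.read_units_csv(path)
    assert [u.unit_id for u in loaded] == [u.unit_id for u in square_units]
    np.testing.assert_allclose(
        [u.attributes for u in loaded], [u.attributes for u in square_units]
    )
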