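import numpy as np
import pytest
from shapely.geometry import Point

from _oracles import brute_distance
from netclus import (InvalidInputError, build_network, network_distance,
                     snap_points, subdivide, weight_matrix)
from netclus.synth import make_grid_network


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_shared_endpoint_becomes_one_node(self):
        net = build_network([[(0, 0), (1, 0)], [(1, 0), (2, 1)]])
        assert net.n_nodes == 3
        assert net.n_edges == 2
        degs = sorted(net.degrees.tolist())
        assert degs == [1, 1, 2]

    def test_crossing_lines_are_noded_on_request(self):
        plus = [[(-1, 0), (1, 0)], [(0, -1), (0, 1)]]
        net = build_network(plus, node_at_crossings=True)
        assert net.n_nodes == 5
        assert net.n_edges == 4
        assert sorted(net.degrees.tolist()) == [1, 1, 1, 1, 4]
        # without noding the crossing stays unnoticed
        flat = build_network(plus)
        assert flat.n_nodes == 4
        assert flat.n_edges == 2

    def test_grid_degrees_match_hand_enumeration(self):
        net = make_grid_network(2, 2, 1.0)
        # inner 3x3 lattice: 4 corners deg 2, 4 edge-mids deg 3, center deg 4
        assert sorted(net.degrees.tolist()) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_empty_and_zero_length_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            build_network([])
        with pytest.raises(InvalidInputError, match="index 1"):
            build_network([[(0, 0), (1, 0)], [(5, 5), (5, 5)]])

    def test_edge_lengths_match_polyline_lengths(self, planar20):
        for e in planar20.edges:
            assert e.length == pytest.approx(e.geometry.length, abs=1e-6)

    def test_degree_equals_incident_edge_count(self, planar20):
        counts = np.zeros(planar20.n_nodes, dtype=int)
        for e in planar20.edges:
            counts[e.node_a] += 1
            counts[e.node_b] += 1
        assert np.array_equal(counts, planar20.degrees)


# ---------------------------------------------------------------------------
# snapping
# ---------------------------------------------------------------------------

class TestSnapPoints:
    def test_point_on_edge_snaps_with_zero_distance(self):
        net = build_network([[(0, 0), (10, 0)]])
        s = snap_points(np.array([[4.0, 0.0]]), net)
        assert s.df.loc[0, "edge_id"] == 0
        assert s.df.loc[0, "offset_m"] == pytest.approx(4.0)
        assert s.df.loc[0, "snap_dist_m"] == pytest.approx(0.0)

    def test_perpendicular_foot(self):
        net = build_network([[(0, 0), (10, 0)]])
        s = snap_points(np.array([[5.0, 3.0]]), net)
        assert s.df.loc[0, "offset_m"] == pytest.approx(5.0)
        assert s.df.loc[0, "snap_dist_m"] == pytest.approx(3.0)

    def test_tie_goes_to_lowest_edge_id(self):
        # two parallel edges; the midpoint is equidistant to both
        net = build_network([[(0, 0), (10, 0)], [(0, 10), (10, 10)]])
        p = np.array([[5.0, 5.0]])
        dists = [net.edges[k].geometry.distance(Point(5, 5))
                 for k in range(net.n_edges)]
        assert dists[0] == pytest.approx(dists[1])  # genuinely tied
        s = snap_points(p, net)
        assert s.df.loc[0, "edge_id"] == 0

    def test_far_points_flagged_and_excluded(self):
        net = build_network([[(0, 0), (10, 0)]])
        s = snap_points(np.array([[5.0, 500.0], [5.0, 1.0]]), net,
                        max_snap_m=100.0)
        assert len(s) == 1
        assert s.n_dropped == 1
        assert len(s.dropped) == 1

    def test_snapping_is_idempotent(self, planar20, rng):
        raw = rng.random((20, 2)) * 500.0
        s1 = snap_points(raw, planar20, max_snap_m=np.inf)
        snapped_xy = s1.coordinates()
        s2 = snap_points(snapped_xy, planar20, max_snap_m=np.inf)
        moved = np.hypot(*(s2.coordinates() - snapped_xy).T)
        assert np.all(moved < 1e-6)


# ---------------------------------------------------------------------------
# subdivision
# ---------------------------------------------------------------------------

class TestSubdivide:
    @pytest.mark.parametrize("unit,expected", [
        (40.0, [40.0, 40.0, 20.0]),
        (100.0, [100.0]),
    ])
    def test_tiling_of_a_100m_edge(self, unit, expected):
        net = build_network([[(0, 0), (100, 0)]])
        units = subdivide(net, unit)
        assert units.lengths.tolist() == pytest.approx(expected)
        if unit == 100.0:
            assert units.df.loc[0, "mid_m"] == pytest.approx(50.0)

    def test_total_length_conserved(self, planar20):
        units = subdivide(planar20, 37.0)
        assert units.lengths.sum() == pytest.approx(
            planar20.total_length, rel=1e-9)
        # tiling is contiguous per edge
        for _, grp in units.df.groupby("edge_id"):
            assert np.allclose(grp["end_m"].to_numpy()[:-1],
                               grp["start_m"].to_numpy()[1:])

    def test_locate_maps_points_to_their_piece(self):
        net = build_network([[(0, 0), (100, 0)]])
        units = subdivide(net, 40.0)
        idx = units.locate(np.zeros(4, dtype=int),
                           np.array([0.0, 39.9, 40.0, 100.0]))
        assert idx.tolist() == [0, 0, 1, 2]

    def test_invalid_unit_rejected(self, grid3):
        with pytest.raises(InvalidInputError):
            subdivide(grid3, 0.0)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestNetworkDistance:
    def test_distance_to_self_is_zero(self, grid3):
        assert network_distance((0, 0.3), (0, 0.3), grid3) == pytest.approx(0)

    def test_single_edge_offsets(self):
        net = build_network([[(0, 0), (100, 0)]])
        assert network_distance((0, 10.0), (0, 60.0), net) == pytest.approx(50)

    def test_disconnected_components_are_infinite(self):
        net = build_network([[(0, 0), (1, 0)], [(10, 10), (11, 10)]])
        assert network_distance((0, 0.5), (1, 0.5), net) == np.inf
        assert net.component_of_location(0) != net.component_of_location(1)

    @pytest.mark.parametrize("net_name", ["grid3", "planar20"])
    def test_matches_brute_force_oracle(self, net_name, rng, request):
        net = request.getfixturevalue(net_name)
        for _ in range(25):
            a = (int(rng.integers(net.n_edges)), 0.0)
            b = (int(rng.integers(net.n_edges)), 0.0)
            a = (a[0], float(rng.random() * net.edge_length[a[0]]))
            b = (b[0], float(rng.random() * net.edge_length[b[0]]))
            assert network_distance(a, b, net) == pytest.approx(
                brute_distance(net, a, b), abs=1e-9)

    def test_node_distances_match_floyd_warshall(self, grid3):
        from scipy.sparse.csgraph import floyd_warshall
        from scipy.sparse import coo_matrix
        rows = [e.node_a for e in grid3.edges]
        cols = [e.node_b for e in grid3.edges]
        m = coo_matrix((grid3.edge_length, (rows, cols)),
                       shape=(grid3.n_nodes,) * 2).tocsr()
        ref = floyd_warshall(m, directed=False)
        for e in grid3.edges[:8]:
            got = grid3.distances_to_nodes(e.edge_id, 0.0)
            np.testing.assert_allclose(got, ref[e.node_a], atol=1e-9)

    def test_metric_properties_on_random_triples(self, planar20, rng):
        def rand_loc():
            e = int(rng.integers(planar20.n_edges))
            return (e, float(rng.random() * planar20.edge_length[e]))
        for _ in range(20):
            a, b, c = rand_loc(), rand_loc(), rand_loc()
            dab = network_distance(a, b, planar20)
            dba = network_distance(b, a, planar20)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert dab <= network_distance(a, c, planar20) + \
                network_distance(c, b, planar20) + 1e-9


# ---------------------------------------------------------------------------
# weight matrices
# ---------------------------------------------------------------------------

class TestWeightMatrix:
    def test_tiny_threshold_gives_empty_matrix(self, grid100,
                                               grid100_segments):
        W = weight_matrix(grid100_segments, grid100, mode="distance",
                          threshold_m=1.0)
        assert W.w.sum() == 0
        assert W.psi == 0.0

    def test_chain_threshold_300_gives_3_neighbors_per_side(self):
        # straight path of ten 100 m segments, center gaps 100/200/300
        net = build_network([[(i * 100.0, 0), ((i + 1) * 100.0, 0)]
                             for i in range(10)])
        segs = subdivide(net, 100.0, kind="segment")
        W = weight_matrix(segs, net, mode="distance", threshold_m=300.0)
        cards = W.cardinalities()
        for i in range(3, 7):      # interior segments
            assert cards[i] == 6
            assert set(W.neighbors(i)) == {i - 3, i - 2, i - 1,
                                           i + 1, i + 2, i + 3}
        # strict mode drops the exactly-300 pair
        Ws = weight_matrix(segs, net, mode="distance", threshold_m=300.0,
                           inclusive=False)
        assert Ws.cardinalities()[5] == 4

    def test_node_mode_links_touching_segments(self):
        net = build_network([[(0, 0), (100, 0)], [(100, 0), (200, 0)]])
        segs = subdivide(net, 50.0, kind="segment")
        W = weight_matrix(segs, net, mode="node")
        # pieces: e0:[0,50),[50,100]; e1:[0,50),[50,100]
        assert W.w[0, 1] == 1            # share interior boundary
        assert W.w[1, 2] == 1            # share the middle graph node
        assert W.w[0, 2] == 0

    def test_symmetry_zero_diagonal_and_psi(self, grid100_W):
        w = grid100_W.w
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert 0.0 <= grid100_W.psi <= 1.0
        # complement partitions the off-diagonal pairs
        comp = grid100_W.complement()
        assert np.all(w + comp + np.eye(len(w), dtype=int) == 1)

    def test_enlarging_threshold_is_monotone(self, grid100, grid100_segments):
        prev = None
        for thr in (150.0, 300.0, 450.0):
            W = weight_matrix(grid100_segments, grid100, mode="distance",
                              threshold_m=thr)
            if prev is not None:
                assert np.all(W.w >= prev)
            prev = W.w

    def test_isolated_components_never_neighbors(self):
        net = build_network([[(0, 0), (100, 0)], [(0, 1000), (100, 1000)]])
        segs = subdivide(net, 100.0, kind="segment")
        W = weight_matrix(segs, net, mode="distance", threshold_m=1e6)
        assert W.w.sum() == 0
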