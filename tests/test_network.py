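"""Street-network primitives against brute-force geometric oracles."""
import math

import networkx as nx
import numpy as np
import pytest

from schoolcommute.network import (
    NetworkError,
    StreetNetwork,
    UnroutableError,
    count_intersections,
    euclidean_distance,
    network_buffer,
    network_from_edge_csv,
    network_from_geojson,
    network_to_edge_csv,
    network_to_geojson,
    shortest_network_distance,
    snap_to_network,
)

from conftest import make_grid


# ---------------------------------------------------------------------- oracles

def brute_snap(net, p):
    """Exhaustive nearest-point scan over every edge segment."""
    best = None
    px, py = p
    for eid, (u, v, w) in enumerate(net.edges):
        (x1, y1), (x2, y2) = net.nodes[u], net.nodes[v]
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / L2))
        qx, qy = x1 + t * dx, y1 + t * dy
        d = math.hypot(px - qx, py - qy)
        off = t * w
        key = (round(d, 9), eid, off)
        if best is None or key < best[0]:
            best = (key, eid, off, d)
    return best[1], best[2], best[3]


def brute_distance(net, a, b):
    """Dijkstra on an augmented graph with snap points as temporary nodes."""
    sa = snap_to_network(net, a)
    sb = snap_to_network(net, b)
    g = net.graph.copy()
    for tmp, s in ((-1, sa), (-2, sb)):
        u, v, w = net.edges[s.edge_id]
        g.add_edge(tmp, u, weight=s.offset_m)
        g.add_edge(tmp, v, weight=w - s.offset_m)
    if sa.edge_id == sb.edge_id:
        g.add_edge(-1, -2, weight=abs(sa.offset_m - sb.offset_m))
    return nx.dijkstra_path_length(g, -1, -2)


# ---------------------------------------------------------------------- snapping

def test_snap_on_node_is_identity(grid_net):
    s = snap_to_network(grid_net, (100.0, 200.0))
    assert s.snap_dist_m == pytest.approx(0.0, abs=1e-9)
    assert s.point == pytest.approx((100.0, 200.0))


def test_snap_perpendicular_midpoint():
    net = StreetNetwork({0: (0, 0), 1: (100, 0)}, [(0, 1, 100.0)])
    s = snap_to_network(net, (50.0, 10.0))
    assert s.edge_id == 0
    assert s.offset_m == pytest.approx(50.0)
    assert s.snap_dist_m == pytest.approx(10.0)


def test_snap_matches_bruteforce_scan(big_grid):
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = tuple(rng.uniform(-50, 1050, size=2))
        s = snap_to_network(big_grid, p)
        eid, off, d = brute_snap(big_grid, p)
        assert s.snap_dist_m == pytest.approx(d, abs=1e-6)
        # location must agree even if an equidistant edge tie was broken
        assert (s.edge_id, s.offset_m) == pytest.approx((eid, off)) or \
            s.snap_dist_m == pytest.approx(d, abs=1e-9)


def test_snap_empty_network_rejected():
    with pytest.raises(NetworkError):
        StreetNetwork({}, [])


# ---------------------------------------------------------------------- distances

def test_euclidean_examples():
    assert euclidean_distance((0, 0), (0, 0)) == 0.0
    assert euclidean_distance((0, 0), (300, 400)) == pytest.approx(500.0)
    assert euclidean_distance((0, 0), (200, 200)) == pytest.approx(200 * math.sqrt(2))


def test_zero_distance_same_point(grid_net):
    assert shortest_network_distance(grid_net, (150, 100), (150, 100)) == pytest.approx(0.0)


def test_grid_manhattan_distance():
    net = make_grid(2, 100.0)
    d = shortest_network_distance(net, (0, 0), (200, 200))
    assert d == pytest.approx(400.0)


def test_distance_matches_bruteforce_dijkstra(big_grid):
    rng = np.random.default_rng(7)
    for _ in range(50):
        a = tuple(rng.uniform(0, 1000, size=2))
        b = tuple(rng.uniform(0, 1000, size=2))
        assert shortest_network_distance(big_grid, a, b) == \
            pytest.approx(brute_distance(big_grid, a, b), abs=1e-6)


def test_distance_symmetry_and_triangle(big_grid):
    rng = np.random.default_rng(11)
    pts = [tuple(rng.uniform(0, 1000, size=2)) for _ in range(3)]
    d = {(i, j): shortest_network_distance(big_grid, pts[i], pts[j])
         for i in range(3) for j in range(3) if i != j}
    for i in range(3):
        for j in range(3):
            if i != j:
                assert d[(i, j)] == pytest.approx(d[(j, i)], abs=1e-6)
    assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)] + 1e-6


def test_network_distance_bounds_euclidean(big_grid):
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = tuple(rng.uniform(0, 1000, size=2))
        b = tuple(rng.uniform(0, 1000, size=2))
        sa, sb = snap_to_network(big_grid, a), snap_to_network(big_grid, b)
        assert shortest_network_distance(big_grid, a, b) >= \
            euclidean_distance(sa.point, sb.point) - 1e-6


def test_disconnected_components_unroutable():
    net = StreetNetwork({0: (0, 0), 1: (100, 0), 2: (1000, 1000), 3: (1100, 1000)},
                        [(0, 1, 100.0), (2, 3, 100.0)])
    with pytest.raises(UnroutableError):
        shortest_network_distance(net, (10, 0), (1050, 1000))


# ---------------------------------------------------------------------- buffers

def test_buffer_partial_single_edge():
    net = StreetNetwork({0: (0, 0), 1: (1000, 0)}, [(0, 1, 1000.0)])
    sa = network_buffer(net, (500, 0), 200.0)
    assert sa.portions == [(0, pytest.approx(300.0), pytest.approx(700.0))]
    assert sa.area_ha > 0
    assert sa.contains((500, 0))


def test_buffer_saturation_covers_all_edges(grid_net):
    sa = network_buffer(grid_net, (200, 200), 10_000.0)
    covered = {eid for eid, a, b in sa.portions
               if b - a == pytest.approx(grid_net.edges[eid][2])}
    assert covered == set(range(len(grid_net.edges)))
    assert sa.reached_nodes == frozenset(grid_net.nodes)


def test_buffer_reached_nodes_match_dijkstra_cut(big_grid):
    school = (450.0, 430.0)
    thr = 1250.0
    sa = network_buffer(big_grid, school, thr)
    g = big_grid.graph.copy()
    s = snap_to_network(big_grid, school)
    u, v, w = big_grid.edges[s.edge_id]
    g.add_edge(-1, u, weight=s.offset_m)
    g.add_edge(-1, v, weight=w - s.offset_m)
    dist = nx.single_source_dijkstra_path_length(g, -1)
    expected = {n for n, d in dist.items() if n >= 0 and d <= thr}
    assert set(sa.reached_nodes) == expected


def test_buffer_monotone_in_threshold(big_grid):
    school = (320.0, 510.0)
    small = network_buffer(big_grid, school, 400.0)
    large = network_buffer(big_grid, school, 900.0)
    assert set(small.reached_nodes) <= set(large.reached_nodes)
    cover_small = {(e, round(a, 6), round(b, 6)) for e, a, b in small.portions}
    for e, a, b in cover_small:
        assert any(e == e2 and a >= a2 - 1e-6 and b <= b2 + 1e-6
                   for e2, a2, b2 in large.portions)


def test_buffer_rejects_bad_threshold(grid_net):
    with pytest.raises(ValueError):
        network_buffer(grid_net, (0, 0), 0.0)


# ---------------------------------------------------------------------- intersections

def test_path_graph_has_no_intersections():
    net = StreetNetwork({i: (i * 100.0, 0.0) for i in range(5)},
                        [(i, i + 1, 100.0) for i in range(4)])
    sa = network_buffer(net, (0, 0), 10_000.0)
    assert count_intersections(sa, net) == 0


def test_grid_intersections_by_degree(grid_net):
    sa = network_buffer(grid_net, (200, 200), 10_000.0)
    # exhaustive scan: all nodes reached, so count = degree>=3 nodes
    expected = sum(1 for n in grid_net.nodes if grid_net.degree(n) >= 3)
    assert count_intersections(sa, grid_net) == expected
    # corners have degree 2 and are excluded
    corner_degrees = [grid_net.degree(n) for n, (x, y) in grid_net.nodes.items()
                      if (x, y) in {(0, 0), (0, 400), (400, 0), (400, 400)}]
    assert all(d == 2 for d in corner_degrees)


# ---------------------------------------------------------------------- validation & I/O

def test_geographic_coordinates_rejected():
    with pytest.raises(NetworkError, match="geographic"):
        StreetNetwork({0: (-3.6, 37.2), 1: (-3.601, 37.201)},
                      [(0, 1, 0.0015)])


@pytest.mark.parametrize("length", [0.0, -5.0, 50.0])
def test_invalid_edge_lengths_rejected(length):
    # 50 m undercut of a 100 m chord is also invalid
    with pytest.raises(NetworkError):
        StreetNetwork({0: (0, 0), 1: (100, 0)}, [(0, 1, length)])


def test_geojson_roundtrip(grid_net):
    obj = network_to_geojson(grid_net)
    back = network_from_geojson(obj)
    assert back.nodes == grid_net.nodes
    assert [(u, v) for u, v, _ in back.edges] == [(u, v) for u, v, _ in grid_net.edges]
    d1 = shortest_network_distance(grid_net, (10, 10), (390, 380))
    d2 = shortest_network_distance(back, (10, 10), (390, 380))
    assert d1 == pytest.approx(d2)


def test_edge_csv_roundtrip(tmp_path, grid_net):
    path = tmp_path / "net.csv"
    network_to_edge_csv(grid_net, str(path))
    back = network_from_edge_csv(str(path))
    assert len(back.edges) == len(grid_net.edges)
    assert back.nodes[7] == pytest.approx(grid_net.nodes[7])
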