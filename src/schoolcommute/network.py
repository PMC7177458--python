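"""Street-network primitives.

The street network is an undirected planar graph with metric edge lengths in a
projected CRS (metres).  Everything downstream — home–school routes, pedestrian
route directness, and school catchment buffers — reduces to three geometric
primitives implemented here: snapping an arbitrary point to the nearest edge,
shortest network distance between two snapped points (partial-edge offsets
included), and a network-distance service area around a school with an
intersection count.
"""
from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import substring, unary_union

__all__ = [
    "NetworkError",
    "UnroutableError",
    "StreetNetwork",
    "Snap",
    "Route",
    "ServiceArea",
    "snap_to_network",
    "euclidean_distance",
    "shortest_network_distance",
    "shortest_route",
    "network_buffer",
    "count_intersections",
    "network_from_geojson",
    "network_to_geojson",
    "network_from_edge_csv",
    "network_to_edge_csv",
    "service_area_to_geojson",
]

#: dilation margin (m) applied to reached edge portions when polygonising a
#: service area — stands in for the pedestrian-accessible strip either side
#: of the carriageway.
DEFAULT_BUFFER_MARGIN_M = 25.0


class NetworkError(ValueError):
    """Invalid network input."""


class UnroutableError(NetworkError):
    """Origin and destination lie in disconnected components."""


@dataclass(frozen=True)
class Snap:
    """A point projected onto the network.

    ``offset_m`` is measured in *weighted* metres from the edge's ``u``
    endpoint (edge weight may exceed chord length for streets digitised as
    straight segments).
    """

    edge_id: int
    offset_m: float
    point: tuple[float, float]
    snap_dist_m: float


@dataclass(frozen=True)
class Route:
    origin: tuple[float, float]
    destination: tuple[float, float]
    nodes: tuple[int, ...]
    network_length_m: float


@dataclass
class ServiceArea:
    """Sub-network reachable within a network-distance threshold of a school."""

    school_point: tuple[float, float]
    threshold_m: float
    reached_nodes: frozenset[int]
    #: list of (edge_id, start_m, end_m) intervals in weighted metres from u
    portions: list[tuple[int, float, float]]
    footprint: shapely.Geometry
    area_ha: float
    school_id: str | None = None

    def contains(self, p: tuple[float, float]) -> bool:
        return self.footprint.covers(Point(p))


class StreetNetwork:
    """Undirected street graph with node coordinates in projected metres.

    Parameters
    ----------
    nodes:
        mapping node id -> (x, y) in metres.
    edges:
        iterable of (u, v, length_m); length may exceed the straight chord
        (curvy street stored as a straight segment) but never undercut it.
    """

    def __init__(self, nodes: Mapping[int, tuple[float, float]],
                 edges: Iterable[tuple[int, int, float]]):
        self.nodes: dict[int, tuple[float, float]] = {
            int(k): (float(v[0]), float(v[1])) for k, v in nodes.items()
        }
        self.edges: list[tuple[int, int, float]] = [
            (int(u), int(v), float(w)) for u, v, w in edges
        ]
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        if not self.nodes or not self.edges:
            raise NetworkError("network must have at least one node and one edge")
        xs = np.array([p[0] for p in self.nodes.values()])
        ys = np.array([p[1] for p in self.nodes.values()])
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            raise NetworkError("node coordinates must be finite")
        max_len = 0.0
        for u, v, w in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise NetworkError(f"edge ({u},{v}) references unknown node")
            if not (w > 0):
                raise NetworkError(f"edge ({u},{v}) has non-positive length {w}")
            chord = math.dist(self.nodes[u], self.nodes[v])
            if w < chord - 1e-6:
                raise NetworkError(
                    f"edge ({u},{v}) length {w} m shorter than chord {chord:.3f} m"
                )
            max_len = max(max_len, w)
        # degrees-looking input: tiny extent inside the lon/lat box with
        # sub-metre edge "lengths" means the caller forgot to project.
        if (np.abs(xs).max() <= 180.0 and np.abs(ys).max() <= 90.0
                and max_len < 1.0):
            raise NetworkError(
                "coordinates look geographic (lon/lat); re-project to a "
                "planar CRS in metres before building a StreetNetwork"
            )

    # -- derived structures ---------------------------------------------
    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for eid, (u, v, w) in enumerate(self.edges):
            g.add_edge(u, v, weight=w, eid=eid)
        return g

    @cached_property
    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {n: [] for n in self.nodes}
        for u, v, w in self.edges:
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj

    @cached_property
    def edge_geoms(self) -> np.ndarray:
        return np.array(
            [LineString([self.nodes[u], self.nodes[v]]) for u, v, _ in self.edges],
            dtype=object,
        )

    def edge_geom(self, eid: int) -> LineString:
        return self.edge_geoms[eid]

    def degree(self, n: int) -> int:
        return len(self.adjacency[n])

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Planar straight-line distance in metres."""
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    if not all(map(math.isfinite, (ax, ay, bx, by))):
        raise ValueError("coordinates must be finite")
    return math.hypot(bx - ax, by - ay)


def snap_to_network(net: StreetNetwork, p: Sequence[float]) -> Snap:
    """Project ``p`` onto the nearest edge segment.

    Ties are broken deterministically: lowest edge id, then lowest offset.
    Offsets are reported in weighted metres (chord offset scaled by the ratio
    of edge weight to chord length).
    """
    pt = Point(float(p[0]), float(p[1]))
    if not (math.isfinite(pt.x) and math.isfinite(pt.y)):
        raise ValueError("cannot snap non-finite coordinates")
    dists = shapely.distance(net.edge_geoms, pt)
    dmin = float(dists.min())
    candidates = np.flatnonzero(dists <= dmin + 1e-9)
    best: tuple[int, float] | None = None
    for eid in sorted(int(c) for c in candidates):
        geom = net.edge_geom(eid)
        chord_off = geom.project(pt)
        u, v, w = net.edges[eid]
        off_w = chord_off * (w / geom.length)
        if best is None or (eid, off_w) < best:
            best = (eid, off_w)
            snap_pt = geom.interpolate(chord_off)
    eid, off_w = best  # type: ignore[misc]
    return Snap(edge_id=eid, offset_m=off_w,
                point=(snap_pt.x, snap_pt.y), snap_dist_m=dmin)


def _dijkstra_from_snap(net: StreetNetwork, snap: Snap,
                        cutoff: float | None = None) -> dict[int, float]:
    """Node distances from a snapped point, seeding the heap with the two
    partial-edge offsets.  Hand-rolled because the source sits mid-edge."""
    u, v, w = net.edges[snap.edge_id]
    seeds = [(snap.offset_m, u), (w - snap.offset_m, v)]
    dist: dict[int, float] = {}
    heap = [(d, n) for d, n in seeds]
    heapq.heapify(heap)
    adj = net.adjacency
    while heap:
        d, n = heapq.heappop(heap)
        if n in dist:
            continue
        if cutoff is not None and d > cutoff:
            continue
        dist[n] = d
        for m, wl in adj[n]:
            if m not in dist:
                heapq.heappush(heap, (d + wl, m))
    return dist


def shortest_network_distance(net: StreetNetwork, origin: Sequence[float],
                              dest: Sequence[float]) -> float:
    """Length (m) of the shortest network path between two snapped points.

    Raises :class:`UnroutableError` when the snapped points fall in
    disconnected components.
    """
    so = snap_to_network(net, origin)
    sd = snap_to_network(net, dest)
    cands = []
    if so.edge_id == sd.edge_id:
        cands.append(abs(so.offset_m - sd.offset_m))
    dist = _dijkstra_from_snap(net, so)
    u, v, w = net.edges[sd.edge_id]
    if u in dist:
        cands.append(dist[u] + sd.offset_m)
    if v in dist:
        cands.append(dist[v] + (w - sd.offset_m))
    if not cands:
        raise UnroutableError("origin and destination are not connected on the network")
    return min(cands)


def shortest_route(net: StreetNetwork, origin: Sequence[float],
                   dest: Sequence[float]) -> Route:
    """Shortest path with the traversed node sequence (diagnostic use)."""
    so = snap_to_network(net, origin)
    sd = snap_to_network(net, dest)
    length = shortest_network_distance(net, origin, dest)
    # node sequence via an augmented graph with temporary snap nodes
    g = net.graph.copy()
    o_id, d_id = -1, -2
    uo, vo, wo = net.edges[so.edge_id]
    ud, vd, wd = net.edges[sd.edge_id]
    g.add_edge(o_id, uo, weight=so.offset_m)
    g.add_edge(o_id, vo, weight=wo - so.offset_m)
    g.add_edge(d_id, ud, weight=sd.offset_m)
    g.add_edge(d_id, vd, weight=wd - sd.offset_m)
    if so.edge_id == sd.edge_id:
        g.add_edge(o_id, d_id, weight=abs(so.offset_m - sd.offset_m))
    try:
        path = nx.dijkstra_path(g, o_id, d_id)
    except nx.NetworkXNoPath as exc:  # pragma: no cover - guarded above
        raise UnroutableError(str(exc)) from exc
    inner = tuple(n for n in path if n >= 0)
    return Route(origin=so.point, destination=sd.point,
                 nodes=inner, network_length_m=length)


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(iv):
        if out and a <= out[-1][1] + 1e-9:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def network_buffer(net: StreetNetwork, school: Sequence[float],
                   threshold_m: float,
                   margin_m: float = DEFAULT_BUFFER_MARGIN_M,
                   school_id: str | None = None) -> ServiceArea:
    """Service area: every edge portion within ``threshold_m`` network metres
    of the school, polygonised by dilating reached portions by ``margin_m``.

    An edge (u, v, L) is covered at position x (weighted metres from u)
    whenever min(d(u) + x, d(v) + L - x) <= threshold; the school's own edge
    additionally gets the direct interval around the snap offset.
    """
    if not (threshold_m > 0):
        raise ValueError("threshold must be positive")
    snap = snap_to_network(net, school)
    dist = _dijkstra_from_snap(net, snap)
    if not dist:
        raise UnroutableError("school does not reach any network node")
    reached_nodes = frozenset(n for n, d in dist.items() if d <= threshold_m)

    portions: list[tuple[int, float, float]] = []
    geoms = []
    for eid, (u, v, w) in enumerate(net.edges):
        iv: list[tuple[float, float]] = []
        du = dist.get(u, math.inf)
        dv = dist.get(v, math.inf)
        if du < threshold_m:
            iv.append((0.0, min(w, threshold_m - du)))
        if dv < threshold_m:
            iv.append((max(0.0, w - (threshold_m - dv)), w))
        if eid == snap.edge_id:
            iv.append((max(0.0, snap.offset_m - threshold_m),
                       min(w, snap.offset_m + threshold_m)))
        for a, b in _merge_intervals(iv):
            if b - a <= 1e-9:
                continue
            portions.append((eid, a, b))
            geom = net.edge_geom(eid)
            scale = geom.length / w
            geoms.append(substring(geom, a * scale, b * scale))
    if not geoms:
        raise UnroutableError("threshold reaches no edge portion")
    footprint = unary_union(geoms).buffer(margin_m)
    return ServiceArea(
        school_point=snap.point,
        threshold_m=float(threshold_m),
        reached_nodes=reached_nodes,
        portions=portions,
        footprint=footprint,
        area_ha=footprint.area / 10_000.0,
        school_id=school_id,
    )


def count_intersections(sa: ServiceArea, net: StreetNetwork) -> int:
    """Number of reached nodes that are true street intersections.

    An intersection is a node of graph degree >= 3 — the standard GIS
    convention, excluding dead-ends and mid-block geometry nodes.
    """
    return sum(1 for n in sa.reached_nodes if net.degree(n) >= 3)


# ---------------------------------------------------------------------------
# I/O — GeoJSON LineString collections and a flat CSV edge-list dialect
# ---------------------------------------------------------------------------

def network_to_geojson(net: StreetNetwork) -> dict:
    feats = []
    for eid, (u, v, w) in enumerate(net.edges):
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [list(net.nodes[u]), list(net.nodes[v])]},
            "properties": {"u": u, "v": v, "length_m": round(w, 3)},
        })
    return {"type": "FeatureCollection", "features": feats}


def network_from_geojson(obj: dict | str) -> StreetNetwork:
    """Read a LineString FeatureCollection.  ``length_m`` is honoured when
    present, recomputed from the geometry otherwise.  Node ids are assigned
    by first appearance of each distinct endpoint unless ``u``/``v``
    properties identify them."""
    if isinstance(obj, str):
        with open(obj) as fh:
            obj = json.load(fh)
    nodes: dict[int, tuple[float, float]] = {}
    coord_ids: dict[tuple[float, float], int] = {}
    edges: list[tuple[int, int, float]] = []

    def node_id(c: tuple[float, float], explicit: int | None) -> int:
        if explicit is not None:
            nodes[int(explicit)] = c
            coord_ids[c] = int(explicit)
            return int(explicit)
        if c not in coord_ids:
            coord_ids[c] = len(coord_ids)
            nodes[coord_ids[c]] = c
        return coord_ids[c]

    for feat in obj["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise NetworkError(f"expected LineString, got {geom.geom_type}")
        props = feat.get("properties") or {}
        cs = list(geom.coords)
        a = (float(cs[0][0]), float(cs[0][1]))
        b = (float(cs[-1][0]), float(cs[-1][1]))
        u = node_id(a, props.get("u"))
        v = node_id(b, props.get("v"))
        w = props.get("length_m")
        edges.append((u, v, float(w) if w is not None else geom.length))
    return StreetNetwork(nodes, edges)


def network_to_edge_csv(net: StreetNetwork, path: str) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["u", "v", "length_m", "x_u", "y_u", "x_v", "y_v"])
        for u, v, w in net.edges:
            xu, yu = net.nodes[u]
            xv, yv = net.nodes[v]
            wr.writerow([u, v, f"{w:.3f}", f"{xu:.3f}", f"{yu:.3f}",
                         f"{xv:.3f}", f"{yv:.3f}"])


def network_from_edge_csv(path: str) -> StreetNetwork:
    import csv

    nodes: dict[int, tuple[float, float]] = {}
    edges: list[tuple[int, int, float]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            u, v = int(row["u"]), int(row["v"])
            nodes[u] = (float(row["x_u"]), float(row["y_u"]))
            nodes[v] = (float(row["x_v"]), float(row["y_v"]))
            edges.append((u, v, float(row["length_m"])))
    return StreetNetwork(nodes, edges)


def service_area_to_geojson(sa: ServiceArea, net: StreetNetwork) -> dict:
    n_int = count_intersections(sa, net)
    return {
        "type": "Feature",
        "geometry": mapping(sa.footprint),
        "properties": {
            "school_id": sa.school_id,
            "threshold_m": sa.threshold_m,
            "area_ha": round(sa.area_ha, 4),
            "n_intersections": n_int,
        },
    }
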