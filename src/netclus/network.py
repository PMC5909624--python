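"""Street-network substrate: graph construction, point snapping, subdivision,
shortest-path distances and segment weight matrices.

The street network is an undirected planar graph ``N = (V, L)`` whose edges
carry metric lengths and polyline geometries in a projected CRS (meters).
Points (collision events, POIs) live *on* the network as ``(edge, offset)``
pairs, offsets measured in meters from the edge's first node along its
polyline.  All distances in this package are shortest-path distances along
the network, never Euclidean.

Conventions
-----------
* Node ids and edge ids are consecutive integers assigned at construction.
* Subdivision pieces tile each edge as half-open intervals
  ``[start, end)`` except the last piece per edge, which is closed.
* Locations in different connected components are at distance ``inf``;
  infinity is a value, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.ops import substring, unary_union
from shapely.strtree import STRtree

from .exceptions import InvalidInputError

#: coordinate tolerance for endpoint noding (meters)
NODE_TOL = 1e-6

#: default snapping tolerance (meters); points farther from every edge are
#: flagged and excluded from analysis sets
DEFAULT_MAX_SNAP_M = 100.0


# ---------------------------------------------------------------------------
# Network data structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    edge_id: int
    node_a: int
    node_b: int
    length: float
    geometry: LineString


class RoadNetwork:
    """Undirected street network with metric edge lengths.

    Parameters are normally not passed directly; use :func:`build_network`.
    """

    def __init__(self, node_coords: np.ndarray, edges: list[Edge]):
        self.node_coords = np.asarray(node_coords, dtype=float)
        self.edges = edges
        g = nx.MultiGraph()
        g.add_nodes_from(range(len(self.node_coords)))
        for e in edges:
            g.add_edge(e.node_a, e.node_b, key=e.edge_id, length=e.length)
        self.graph = g
        self.edge_node_a = np.array([e.node_a for e in edges], dtype=np.intp)
        self.edge_node_b = np.array([e.node_b for e in edges], dtype=np.intp)
        self.edge_length = np.array([e.length for e in edges], dtype=float)
        self.degrees = np.array([g.degree(v) for v in range(len(self.node_coords))],
                                dtype=np.intp)
        comp = np.empty(len(self.node_coords), dtype=np.intp)
        for cid, nodes in enumerate(nx.connected_components(g)):
            comp[list(nodes)] = cid
        self._component = comp
        self._tree: STRtree | None = None

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def degree(self, node: int) -> int:
        return int(self.degrees[node])

    def component_of_node(self, node: int) -> int:
        return int(self._component[node])

    def component_of_location(self, edge_id: int, offset_m: float = 0.0) -> int:
        return int(self._component[self.edges[edge_id].node_a])

    def point_at(self, edge_id: int, offset_m: float) -> Point:
        """Coordinates of the on-network location (edge, offset)."""
        return self.edges[edge_id].geometry.interpolate(offset_m)

    def _strtree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree([e.geometry for e in self.edges])
        return self._tree

    # -- distances ----------------------------------------------------------

    def distances_to_nodes(self, edge_id: int, offset_m: float) -> np.ndarray:
        """Network distance from an on-edge location to every node.

        Unreachable nodes (other components) get ``inf``.
        """
        e = self.edges[edge_id]
        d = np.full(self.n_nodes, np.inf)
        da = nx.single_source_dijkstra_path_length(self.graph, e.node_a,
                                                   weight="length")
        db = nx.single_source_dijkstra_path_length(self.graph, e.node_b,
                                                   weight="length")
        for v, dist in da.items():
            d[v] = offset_m + dist
        for v, dist in db.items():
            d[v] = min(d[v], (e.length - offset_m) + dist)
        return d

    def distances_to_locations(self, src_edge: int, src_offset: float,
                               edge_ids: np.ndarray,
                               offsets: np.ndarray) -> np.ndarray:
        """Network distances from one location to many, vectorized.

        Uses the endpoint decomposition d(a,b) = min over entry nodes of
        b's edge, plus the direct along-edge candidate when a and b share
        an edge.
        """
        edge_ids = np.asarray(edge_ids, dtype=np.intp)
        offsets = np.asarray(offsets, dtype=float)
        dn = self.distances_to_nodes(src_edge, src_offset)
        return combine_node_distances(self, dn, src_edge, src_offset,
                                      edge_ids, offsets)


def combine_node_distances(net: RoadNetwork, node_dists: np.ndarray,
                           src_edge: int, src_offset: float,
                           edge_ids: np.ndarray,
                           offsets: np.ndarray) -> np.ndarray:
    """Combine per-node distances from a source location into distances to
    arbitrary (edge, offset) targets."""
    na = net.edge_node_a[edge_ids]
    nb = net.edge_node_b[edge_ids]
    ln = net.edge_length[edge_ids]
    d = np.minimum(node_dists[na] + offsets, node_dists[nb] + (ln - offsets))
    same = edge_ids == src_edge
    if np.any(same):
        d[same] = np.minimum(d[same], np.abs(offsets[same] - src_offset))
    return d


def network_distance(a: tuple[int, float], b: tuple[int, float],
                     net: RoadNetwork,
                     inserted: Sequence[tuple[int, float]] | None = None) -> float:
    """Shortest-path distance between two on-network locations.

    ``inserted`` lists additional on-network locations treated as temporary
    nodes; because inserting a degree-2 node on an edge never changes path
    lengths, it does not affect the metric and is accepted for interface
    compatibility only.

    Returns ``inf`` when the locations lie in different components.
    """
    ea, oa = a
    eb, ob = b
    d = net.distances_to_locations(ea, float(oa),
                                   np.array([eb], dtype=np.intp),
                                   np.array([ob], dtype=float))
    return float(d[0])


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _as_linestrings(lines: Iterable) -> list[LineString]:
    out = []
    for obj in lines:
        if isinstance(obj, LineString):
            out.append(obj)
        else:
            out.append(LineString(obj))
    return out


def build_network(lines: Iterable, node_at_crossings: bool = False) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from polylines.

    Nodes are created at shared polyline endpoints (coordinates equal within
    ``NODE_TOL``).  With ``node_at_crossings`` enabled, interior geometric
    crossings are also noded and the crossing lines split — use this when
    the input layer is not already noded at intersections.
    """
    geoms = _as_linestrings(lines)
    if len(geoms) == 0:
        raise InvalidInputError("empty line collection")
    for idx, g in enumerate(geoms):
        if len(g.coords) < 2 or g.length <= 0.0:
            raise InvalidInputError(f"zero-length or degenerate line at index {idx}")

    if node_at_crossings:
        merged = unary_union(geoms)
        if isinstance(merged, LineString):
            geoms = [merged]
        else:
            geoms = [g for g in merged.geoms if isinstance(g, LineString)]

    node_ids: dict[tuple[float, float], int] = {}
    coords: list[tuple[float, float]] = []

    def node_for(xy) -> int:
        key = (round(xy[0] / NODE_TOL) * NODE_TOL, round(xy[1] / NODE_TOL) * NODE_TOL)
        nid = node_ids.get(key)
        if nid is None:
            nid = len(coords)
            node_ids[key] = nid
            coords.append((xy[0], xy[1]))
        return nid

    edges: list[Edge] = []
    for g in geoms:
        cs = list(g.coords)
        a = node_for(cs[0])
        b = node_for(cs[-1])
        edges.append(Edge(len(edges), a, b, g.length, g))
    return RoadNetwork(np.array(coords, dtype=float), edges)


# ---------------------------------------------------------------------------
# Point snapping
# ---------------------------------------------------------------------------

class SnappedPointSet:
    """Points located on the network as (edge, offset) with attributes.

    ``df`` carries one row per retained point with at least the columns
    ``edge_id, offset_m, snap_dist_m``; any further columns (timestamps,
    loss values, POI categories...) ride along verbatim.
    """

    def __init__(self, df: pd.DataFrame, net: RoadNetwork,
                 n_dropped: int = 0, dropped: pd.DataFrame | None = None):
        self.df = df.reset_index(drop=True)
        self.net = net
        self.n_dropped = n_dropped
        self.dropped = dropped
        if len(df) and not np.all(np.isin(df["edge_id"].to_numpy(),
                                          np.arange(net.n_edges))):
            raise InvalidInputError("snapped point references unknown edge")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def edge_ids(self) -> np.ndarray:
        return self.df["edge_id"].to_numpy(dtype=np.intp)

    @property
    def offsets(self) -> np.ndarray:
        return self.df["offset_m"].to_numpy(dtype=float)

    def locations(self) -> list[tuple[int, float]]:
        return list(zip(self.edge_ids.tolist(), self.offsets.tolist()))

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of on-network coordinates."""
        pts = [self.net.point_at(e, o) for e, o in
               zip(self.edge_ids, self.offsets)]
        return np.array([[p.x, p.y] for p in pts]) if pts else np.empty((0, 2))

    def subset(self, mask: np.ndarray) -> "SnappedPointSet":
        return SnappedPointSet(self.df.loc[np.asarray(mask)].copy(), self.net)


def snap_points(points: pd.DataFrame | np.ndarray, net: RoadNetwork,
                max_snap_m: float = DEFAULT_MAX_SNAP_M,
                x_col: str = "x", y_col: str = "y") -> SnappedPointSet:
    """Snap raw x/y points to their nearest network edge.

    Each point is assigned to the geometrically nearest edge (perpendicular
    projection clamped to the edge); ties on distance go to the lowest edge
    id, which makes the assignment deterministic and order-independent.
    Points farther than ``max_snap_m`` from every edge are excluded and
    reported via ``n_dropped`` / ``dropped``.
    """
    if isinstance(points, np.ndarray):
        points = pd.DataFrame(points[:, :2], columns=[x_col, y_col])
    if x_col not in points.columns or y_col not in points.columns:
        raise InvalidInputError(f"point table lacks '{x_col}'/'{y_col}' columns")

    tree = net._strtree()
    xs = points[x_col].to_numpy(dtype=float)
    ys = points[y_col].to_numpy(dtype=float)
    edge_id = np.empty(len(points), dtype=np.intp)
    offset = np.empty(len(points), dtype=float)
    snapd = np.empty(len(points), dtype=float)
    for i, (x, y) in enumerate(zip(xs, ys)):
        p = Point(x, y)
        nearest_idx = tree.nearest(p)
        dmin = net.edges[nearest_idx].geometry.distance(p)
        # tie rule: all edges within NODE_TOL of the minimum, lowest id wins
        cand = tree.query(p, predicate="dwithin", distance=dmin + NODE_TOL)
        best = int(np.min(cand)) if len(cand) else int(nearest_idx)
        geom = net.edges[best].geometry
        edge_id[i] = best
        offset[i] = min(max(geom.project(p), 0.0), geom.length)
        snapd[i] = geom.distance(p)

    df = points.copy().reset_index(drop=True)
    df["edge_id"] = edge_id
    df["offset_m"] = offset
    df["snap_dist_m"] = snapd
    keep = snapd <= max_snap_m
    dropped = df.loc[~keep].copy()
    return SnappedPointSet(df.loc[keep].copy(), net,
                           n_dropped=int((~keep).sum()), dropped=dropped)


# ---------------------------------------------------------------------------
# Subdivision: lixels and segments
# ---------------------------------------------------------------------------

class LinearUnits:
    """Equal-length subdivision of the network (lixels or analysis segments).

    Pieces tile each edge exactly: contiguous, non-overlapping, their union
    is the edge; every piece has the target length except possibly the last
    per edge.
    """

    def __init__(self, df: pd.DataFrame, net: RoadNetwork, target_length_m: float):
        self.df = df.reset_index(drop=True)
        self.net = net
        self.target_length_m = target_length_m
        # per-edge piece boundaries for O(log k) location lookup
        self._by_edge: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for eid, grp in self.df.groupby("edge_id"):
            self._by_edge[int(eid)] = (grp["start_m"].to_numpy(),
                                       grp.index.to_numpy(dtype=np.intp))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return self.df["length_m"].to_numpy(dtype=float)

    @property
    def edge_ids(self) -> np.ndarray:
        return self.df["edge_id"].to_numpy(dtype=np.intp)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit midpoints as (edge_ids, offsets)."""
        return (self.edge_ids, self.df["mid_m"].to_numpy(dtype=float))

    def locate(self, edge_ids: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        """Map on-network locations to unit indices (half-open pieces,
        last piece per edge closed)."""
        edge_ids = np.asarray(edge_ids, dtype=np.intp)
        offsets = np.asarray(offsets, dtype=float)
        out = np.empty(len(edge_ids), dtype=np.intp)
        for i, (e, o) in enumerate(zip(edge_ids, offsets)):
            starts, idx = self._by_edge[int(e)]
            j = int(np.searchsorted(starts, o, side="right")) - 1
            j = min(max(j, 0), len(idx) - 1)
            out[i] = idx[j]
        return out

    def count_events(self, points: SnappedPointSet,
                     mask: np.ndarray | None = None) -> np.ndarray:
        """Per-unit event counts (optionally restricted by a boolean mask
        over the points)."""
        e, o = points.edge_ids, points.offsets
        if mask is not None:
            m = np.asarray(mask, dtype=bool)
            e, o = e[m], o[m]
        counts = np.zeros(len(self), dtype=np.int64)
        if len(e):
            np.add.at(counts, self.locate(e, o), 1)
        return counts

    def geometries(self) -> list[LineString]:
        return [substring(self.net.edges[int(r.edge_id)].geometry,
                          r.start_m, r.end_m)
                for r in self.df.itertuples()]


class LixelSet(LinearUnits):
    """Fine subdivision used as density evaluation/output units."""


class SegmentSet(LinearUnits):
    """Coarse subdivision used as the analysis unit for local statistics."""


def subdivide(net: RoadNetwork, unit_length_m: float,
              kind: str = "lixel") -> LinearUnits:
    """Split every edge into ⌈length/unit⌉ pieces of the given unit length
    (the last piece per edge takes the remainder)."""
    if unit_length_m <= 0:
        raise InvalidInputError("unit_length_m must be > 0")
    rows = []
    for e in net.edges:
        n = max(1, math.ceil(e.length / unit_length_m - 1e-12))
        bounds = [min(i * unit_length_m, e.length) for i in range(n)] + [e.length]
        for i in range(n):
            s, t = bounds[i], bounds[i + 1]
            mid = 0.5 * (s + t)
            p = e.geometry.interpolate(mid)
            rows.append((e.edge_id, s, t, t - s, mid, p.x, p.y))
    df = pd.DataFrame(rows, columns=["edge_id", "start_m", "end_m",
                                     "length_m", "mid_m", "mid_x", "mid_y"])
    cls = LixelSet if kind == "lixel" else SegmentSet
    return cls(df, net, unit_length_m)


# ---------------------------------------------------------------------------
# Segment weight matrices
# ---------------------------------------------------------------------------

class NetworkWeightMatrix:
    """Binary segment-adjacency matrix W_N with zero diagonal.

    ``psi`` is the share of neighbor pairs among all ordered pairs,
    ψ = ΣΣ w_ij / (n(n−1)); the complement W̄ = J − W − I covers the
    non-neighbor pairs.
    """

    def __init__(self, w: np.ndarray, mode: str = "custom",
                 threshold_m: float | None = None):
        w = np.asarray(w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError("weight matrix must be square")
        if not np.array_equal(w, w.T):
            raise InvalidInputError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidInputError("weight matrix must have zero diagonal")
        self.w = w.astype(np.int8)
        self.mode = mode
        self.threshold_m = threshold_m

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def psi(self) -> float:
        n = self.n
        if n < 2:
            return 0.0
        return float(self.w.sum()) / (n * (n - 1))

    def complement(self) -> np.ndarray:
        """W̄ = J − W − I."""
        return (np.ones_like(self.w) - self.w - np.eye(self.n, dtype=np.int8)
                ).astype(np.int8)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.w[i])

    def cardinalities(self) -> np.ndarray:
        return self.w.sum(axis=1)


def weight_matrix(segs: LinearUnits, net: RoadNetwork,
                  mode: str = "distance", threshold_m: float = 300.0,
                  inclusive: bool = True) -> NetworkWeightMatrix:
    """Segment weight matrix.

    distance mode: w_ij = 1 iff the network distance between segment centers
    is within ``threshold_m`` (``inclusive`` controls ≤ vs <); node mode:
    w_ij = 1 iff the segments share an endpoint location (a graph node or a
    common subdivision boundary).
    """
    n = len(segs)
    w = np.zeros((n, n), dtype=np.int8)
    if mode == "node":
        keys: dict[tuple, list[int]] = {}
        for i, r in enumerate(segs.df.itertuples()):
            e = net.edges[int(r.edge_id)]
            for off, node in ((r.start_m, e.node_a), (r.end_m, e.node_b)):
                if off <= NODE_TOL:
                    key = ("node", e.node_a)
                elif off >= e.length - NODE_TOL:
                    key = ("node", e.node_b)
                else:
                    key = ("edge", int(r.edge_id), round(off, 6))
                keys.setdefault(key, []).append(i)
        for members in keys.values():
            for i in members:
                for j in members:
                    if i != j:
                        w[i, j] = 1
    elif mode == "distance":
        if threshold_m <= 0:
            raise InvalidInputError("distance mode requires threshold_m > 0")
        ce, co = segs.centers()
        for i in range(n):
            d = net.distances_to_locations(int(ce[i]), float(co[i]), ce, co)
            hit = (d <= threshold_m + 1e-9) if inclusive else (d < threshold_m)
            w[i, hit] = 1
            w[i, i] = 0
        w = np.maximum(w, w.T)  # guard float asymmetry at the threshold
    else:
        raise InvalidInputError(f"unknown weight-matrix mode: {mode}")
    return NetworkWeightMatrix(w, mode=mode, threshold_m=threshold_m)
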