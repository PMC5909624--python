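"""Synthetic networks and event data for testing the network statistics.

The study inputs this emulates are street networks in a projected metric
CRS, collision events with timestamps and a heavily zero-inflated direct
financial loss attribute, typed POI points, and per-segment two-period
counts.  Three network recipes are provided:

* ``grid``: rows × cols lattice of square cells with a given spacing, each
  cell side its own edge — degrees and counts are hand-checkable;
* ``ring``: a single closed cycle (no boundary, all degrees 2) — the
  right substrate for kernel mass-conservation checks;
* ``random_planar``: Delaunay triangulation of uniform random points —
  connected, planar, irregular degrees.

Events are sampled uniformly with respect to length (CSR) or with the
intensity multiplied on a named set of hotspot segments.  Two-period
counts are independent Poisson draws per segment-period with a planted
rate change on selected segments.  Timestamps follow an hour-of-day
profile with a daytime plateau and a deep night trough so period binning
is exercised; the loss attribute is a zero-inflated lognormal whose shape
(dominant zeros, rare large losses) mirrors real collision loss tables.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .moran import PeriodCounts
from .network import (LinearUnits, RoadNetwork, SnappedPointSet,
                      build_network)

__all__ = [
    "make_grid_network",
    "make_ring_network",
    "make_random_planar_network",
    "make_network",
    "make_events",
    "make_two_period_counts",
    "DEFAULT_HOUR_WEIGHTS",
    "LOSS_ZERO_PROB",
]

#: hourly intensity weights (local clock, 24 entries): deep trough 2–6,
#: plateau through the day, shoulder late evening
DEFAULT_HOUR_WEIGHTS = np.array(
    [3, 2, 1, 1, 1, 1, 4, 6, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 7, 7, 6, 5, 4, 3],
    dtype=float)

#: probability of zero direct financial loss (fixture constant chosen to
#: mimic the dominant-zero shape of real collision loss tables)
LOSS_ZERO_PROB = 0.92


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Network recipes
# ---------------------------------------------------------------------------

def make_grid_network(rows: int, cols: int, spacing: float = 100.0) -> RoadNetwork:
    """rows × cols lattice of square cells; (rows+1)(cols+1) nodes, each
    cell side a separate edge of the given spacing."""
    if rows < 1 or cols < 1 or spacing <= 0:
        raise InvalidInputError("grid needs rows, cols >= 1 and spacing > 0")
    lines = []
    for r in range(rows + 1):
        for c in range(cols):
            lines.append([(c * spacing, r * spacing),
                          ((c + 1) * spacing, r * spacing)])
    for r in range(rows):
        for c in range(cols + 1):
            lines.append([(c * spacing, r * spacing),
                          (c * spacing, (r + 1) * spacing)])
    return build_network(lines)


def make_ring_network(circumference: float, n_arcs: int = 64) -> RoadNetwork:
    """Single closed cycle of total length ``circumference`` built from
    ``n_arcs`` chord edges; every node has degree 2."""
    if circumference <= 0 or n_arcs < 3:
        raise InvalidInputError("ring needs circumference > 0 and n_arcs >= 3")
    # regular n-gon whose perimeter equals the requested circumference
    side = circumference / n_arcs
    radius = side / (2.0 * np.sin(np.pi / n_arcs))
    ang = 2.0 * np.pi * np.arange(n_arcs + 1) / n_arcs
    xs, ys = radius * np.cos(ang), radius * np.sin(ang)
    lines = [[(xs[i], ys[i]), (xs[i + 1], ys[i + 1])] for i in range(n_arcs)]
    return build_network(lines)


def make_random_planar_network(n_nodes: int, extent: float = 1000.0,
                               seed: int | None = None) -> RoadNetwork:
    """Connected planar network from the Delaunay triangulation of
    ``n_nodes`` uniform random points in a square of side ``extent``."""
    if n_nodes < 3:
        raise InvalidInputError("need at least 3 nodes")
    from scipy.spatial import Delaunay
    rng = _rng(seed)
    pts = rng.random((n_nodes, 2)) * extent
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[a], simplex[b]))
            edges.add((i, j))
    lines = [[tuple(pts[i]), tuple(pts[j])] for i, j in sorted(edges)]
    return build_network(lines)


def make_network(recipe: dict) -> RoadNetwork:
    """Dispatch on ``recipe["kind"]`` ∈ {grid, ring, random_planar}."""
    kind = recipe.get("kind")
    if kind == "grid":
        return make_grid_network(recipe["rows"], recipe["cols"],
                                 recipe.get("spacing", 100.0))
    if kind == "ring":
        return make_ring_network(recipe["circumference"],
                                 recipe.get("n_arcs", 64))
    if kind == "random_planar":
        return make_random_planar_network(recipe["n_nodes"],
                                          recipe.get("extent", 1000.0),
                                          recipe.get("seed"))
    raise InvalidInputError(f"unknown network recipe: {kind!r}")


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def _draw_timestamps(n: int, rng: np.random.Generator,
                     start: str = "2016-07-01",
                     days: int = 184) -> pd.Series:
    """Timestamps over a study window with the default hour-of-day profile;
    dates uniform over the window (so weekday/weekend splits work)."""
    day = rng.integers(0, days, size=n)
    hw = DEFAULT_HOUR_WEIGHTS / DEFAULT_HOUR_WEIGHTS.sum()
    hour = rng.choice(24, size=n, p=hw)
    frac = rng.random(n)
    t0 = pd.Timestamp(start)
    return pd.Series(t0 + pd.to_timedelta(day, "D")
                     + pd.to_timedelta(hour, "h")
                     + pd.to_timedelta(frac * 3600.0, "s"))


def _draw_losses(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-inflated lognormal loss values (Yuan): mostly zero, rare large."""
    loss = np.zeros(n)
    nz = rng.random(n) >= LOSS_ZERO_PROB
    k = int(nz.sum())
    if k:
        loss[nz] = np.round(np.exp(rng.normal(np.log(600.0), 0.9, size=k)))
    return loss


def make_events(net: RoadNetwork, n: int, seed: int | None = None,
                segments: LinearUnits | None = None,
                hotspot_ids: np.ndarray | list | tuple = (),
                multiplier: float = 1.0,
                timestamps: bool = True,
                losses: bool = True) -> SnappedPointSet:
    """Sample ``n`` events on the network.

    Without ``segments`` the sampling is CSR over edges (probability ∝
    edge length, offset uniform).  With ``segments`` the sampling units are
    the segments, with intensity ∝ length times ``multiplier`` on the
    segments listed in ``hotspot_ids``; a multiplier of 1 is exactly CSR.
    """
    if n < 0:
        raise InvalidInputError("n must be >= 0")
    if multiplier <= 0:
        raise InvalidInputError("multiplier must be > 0")
    rng = _rng(seed)
    if segments is None:
        lengths = net.edge_length
        unit_edges = np.arange(net.n_edges, dtype=np.intp)
        unit_starts = np.zeros(net.n_edges)
    else:
        lengths = segments.lengths.copy()
        unit_edges = segments.edge_ids
        unit_starts = segments.df["start_m"].to_numpy(dtype=float)
    weights = lengths.astype(float).copy()
    if len(hotspot_ids):
        if segments is None:
            raise InvalidInputError("hotspot_ids requires a SegmentSet")
        weights[np.asarray(hotspot_ids, dtype=np.intp)] *= multiplier
    p = weights / weights.sum()
    units = rng.choice(len(weights), size=n, p=p)
    offs = unit_starts[units] + rng.random(n) * lengths[units]
    df = pd.DataFrame({"edge_id": unit_edges[units], "offset_m": offs,
                       "snap_dist_m": np.zeros(n)})
    if timestamps:
        df["timestamp"] = _draw_timestamps(n, rng)
    if losses:
        df["loss"] = _draw_losses(n, rng)
    return SnappedPointSet(df, net)


# ---------------------------------------------------------------------------
# Two-period counts
# ---------------------------------------------------------------------------

def make_two_period_counts(segs: LinearUnits, seed: int | None = None,
                           base_rate_per_day: float = 2.0,
                           L: tuple[float, float] = (5.0, 2.0),
                           hotspot_ids: np.ndarray | list | tuple = (),
                           multiplier: float = 1.0) -> PeriodCounts:
    """Independent Poisson counts per segment-period.

    Period 1 rate is ``base_rate_per_day``·L1 on every segment; period 2
    multiplies the rate by ``multiplier`` on the planted segments.  The
    default period lengths (5, 2) match a weekday/weekend layout.
    """
    if base_rate_per_day < 0:
        raise InvalidInputError("base rate must be >= 0")
    if multiplier <= 0:
        raise InvalidInputError("multiplier must be > 0")
    rng = _rng(seed)
    n = len(segs)
    L1, L2 = L
    rate2 = np.full(n, base_rate_per_day)
    if len(hotspot_ids):
        rate2[np.asarray(hotspot_ids, dtype=np.intp)] *= multiplier
    v1 = rng.poisson(base_rate_per_day * L1, size=n)
    v2 = rng.poisson(rate2 * L2, size=n)
    return PeriodCounts(v_t1=v1, v_t2=v2, L_t1=L1, L_t2=L2)
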