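"""Readers/writers, analysis configuration and period binning.

Geometry moves as GeoJSON (LineString layers for streets and lixel/segment
outputs, Point layers for events and POIs); tables as CSV.  All
coordinates must be in one projected metric CRS; the CRS is carried as an
opaque identifier string in a ``crs`` member of the GeoJSON object and is
never transformed — reprojection is the caller's job.  Every analysis
output is accompanied by a sidecar JSON metadata record (package version,
configuration, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, Point, mapping, shape

from .exceptions import InvalidInputError

log = logging.getLogger("netclus")

HOUR_BINS = ((2, 6), (6, 10), (10, 14), (14, 18), (18, 22), (22, 2))
HOUR_BIN_LABELS = tuple(f"{a}-{b}" for a, b in HOUR_BINS)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the full workflow with the field defaults:
    200 m bandwidth, 40 m lixels, 100 m analysis segments, 300 m
    distance-band weights, [1, 10] weight interval, 999 permutations /
    simulations at α = 0.05, 100 m snap tolerance."""

    bandwidth_m: float = 200.0
    lixel_m: float = 40.0
    segment_m: float = 100.0
    weight_threshold_m: float = 300.0
    weight_mode: str = "distance"
    n_perm: int = 999
    n_sim: int = 999
    alpha: float = 0.05
    weight_interval: tuple[float, float] = (1.0, 10.0)
    weight_order: str = "as-printed"
    kernel: str = "quartic"
    max_snap_m: float = 100.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("bandwidth_m", "lixel_m", "segment_m",
                     "weight_threshold_m", "max_snap_m"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if not (0 < self.alpha < 1):
            raise InvalidInputError("alpha must be in (0, 1)")
        if self.n_perm < 1 or self.n_sim < 1:
            raise InvalidInputError("n_perm and n_sim must be >= 1")
        lo, hi = self.weight_interval
        if lo > hi:
            raise InvalidInputError("weight_interval must be ordered")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load overrides from a plain key-value (YAML-subset) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidInputError("config file must hold key: value pairs")
        if "weight_interval" in data:
            data["weight_interval"] = tuple(data["weight_interval"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weight_interval"] = list(self.weight_interval)
        return d


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

def _read_geojson(path: str | Path, want: str, require_crs: bool):
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InvalidInputError(f"unreadable GeoJSON {path}: {exc}") from exc
    if obj.get("type") != "FeatureCollection":
        raise InvalidInputError(f"{path}: expected a FeatureCollection")
    crs = obj.get("crs")
    if isinstance(crs, dict):     # legacy named-CRS form
        crs = crs.get("properties", {}).get("name")
    if require_crs and not crs:
        raise InvalidInputError(f"{path}: missing CRS metadata "
                                "(coordinates must be projected meters)")
    geoms, props = [], []
    for i, feat in enumerate(obj.get("features", [])):
        g = shape(feat["geometry"])
        if g.geom_type != want:
            raise InvalidInputError(
                f"{path}: feature {i} is {g.geom_type}, expected {want}")
        geoms.append(g)
        props.append(feat.get("properties") or {})
    return geoms, pd.DataFrame(props), crs


def read_lines(path: str | Path, require_crs: bool = True
               ) -> tuple[list[LineString], pd.DataFrame, str | None]:
    """Street polylines with their attribute table and CRS identifier."""
    return _read_geojson(path, "LineString", require_crs)


def read_geojson_points(path: str | Path, require_crs: bool = True
                        ) -> tuple[pd.DataFrame, str | None]:
    """Point layer as a table with x, y plus the feature attributes."""
    geoms, props, crs = _read_geojson(path, "Point", require_crs)
    props = props.copy()
    props["x"] = [g.x for g in geoms]
    props["y"] = [g.y for g in geoms]
    return props, crs


def read_points(path: str | Path, x_col: str = "x", y_col: str = "y",
                time_col: str | None = None,
                require_crs: bool = True) -> tuple[pd.DataFrame, str | None]:
    """Raw point table from CSV or GeoJSON.

    Timestamps, when present, are parsed to a timezone-naive local clock.
    CSV carries no CRS; the caller asserts the coordinates match the
    street layer's CRS.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df, crs = read_geojson_points(path, require_crs=require_crs)
    else:
        if not path.exists():
            raise InvalidInputError(f"file not found: {path}")
        df, crs = pd.read_csv(path), None
        for col in (x_col, y_col):
            if col not in df.columns:
                raise InvalidInputError(f"{path}: missing column '{col}'")
        df = df.rename(columns={x_col: "x", y_col: "y"})
    if time_col and time_col in df.columns:
        df[time_col] = pd.to_datetime(df[time_col]).dt.tz_localize(None) \
            if df[time_col].dtype == object else pd.to_datetime(df[time_col])
    return df, crs


def write_lines(path: str | Path, geometries: list[LineString],
                properties: pd.DataFrame | None = None,
                crs: str | None = None) -> None:
    feats = []
    for i, g in enumerate(geometries):
        props = ({} if properties is None
                 else json.loads(properties.iloc[i].to_json()))
        feats.append({"type": "Feature", "geometry": mapping(g),
                      "properties": props})
    obj = {"type": "FeatureCollection", "features": feats}
    if crs:
        obj["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_points(path: str | Path, df: pd.DataFrame,
                 crs: str | None = None) -> None:
    feats = []
    for _, row in df.iterrows():
        props = {k: v for k, v in row.items() if k not in ("x", "y")}
        props = json.loads(pd.Series(props).to_json())
        feats.append({"type": "Feature",
                      "geometry": mapping(Point(row["x"], row["y"])),
                      "properties": props})
    obj = {"type": "FeatureCollection", "features": feats}
    if crs:
        obj["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_sidecar(path: str | Path, config: AnalysisConfig,
                  extra: dict | None = None) -> None:
    """Run-metadata record written next to every output table."""
    from . import __version__
    meta = {"package": "netclus", "version": __version__,
            "config": config.to_dict()}
    if extra:
        meta.update(extra)
    with open(Path(path).with_suffix(Path(path).suffix + ".meta.json"),
              "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Period binning
# ---------------------------------------------------------------------------

def hour_bin(timestamps: pd.Series) -> np.ndarray:
    """Assign each timestamp to one of the hour-of-day bins
    [2,6), [6,10), [10,14), [14,18), [18,22), [22,2) — the last wraps
    midnight.  Returns the bin labels."""
    hours = pd.to_datetime(timestamps).dt.hour.to_numpy()
    out = np.empty(len(hours), dtype=object)
    for (a, b), lab in zip(HOUR_BINS, HOUR_BIN_LABELS):
        mask = ((hours >= a) & (hours < b)) if a < b \
            else ((hours >= a) | (hours < b))
        out[mask] = lab
    return out


def is_weekend(timestamps: pd.Series) -> np.ndarray:
    return pd.to_datetime(timestamps).dt.dayofweek.to_numpy() >= 5
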