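"""Readers, writers, and detection-quality filters for telemetry tables.

File dialects
-------------
``detections.csv``   timestamp (ISO-8601, stored UTC), receiver_id, tag_id
``receivers.csv``    receiver_id, lat, lon, depth, in_kelp
``deployments.csv``  tag_id, release_time, release_lat, release_lon,
                     total_length, min_interval, max_interval, battery_days
polygons             GeoJSON FeatureCollection (RFC 7946, WGS84 lon-lat),
                     each feature carrying a ``role`` property out of
                     {mpa_no_take, conservation_area, land}

Timestamps are stored UTC internally; every day-resolution operation
(tagging-day filter, days-at-liberty, detection-day counts) interprets them
in a configured local zone, because field days are civil local days.

Two quality filters are applied before any analysis:

* tagging-day filter — drops every detection logged on the local calendar
  date the fish was released, to exclude post-handling behaviour;
* code-collision filter — within each (tag, receiver) stream, drops any
  detection closer than a minimum plausible gap (default: the tag's
  minimum programmed delay, 30 s) to the last *retained* detection, a
  deterministic single-pass rule that keeps the earlier record of a pair.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.validation import explain_validity

logger = logging.getLogger(__name__)

DEFAULT_TZ = "America/Los_Angeles"

DETECTION_COLUMNS = ["timestamp", "receiver_id", "tag_id"]
RECEIVER_COLUMNS = ["receiver_id", "lat", "lon", "depth", "in_kelp"]
DEPLOYMENT_COLUMNS = [
    "tag_id", "release_time", "release_lat", "release_lon",
    "total_length", "min_interval", "max_interval", "battery_days",
]

POLYGON_ROLES = {"mpa_no_take", "conservation_area", "land"}


@dataclass(frozen=True)
class ReceiverStation:
    """A georeferenced moored listening station."""

    receiver_id: str
    lat: float
    lon: float
    depth: float  # metres, positive down
    in_kelp: bool = False

    def __post_init__(self):
        if not self.receiver_id:
            raise ValueError("receiver_id must be non-empty")
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError(f"coordinates out of range: ({self.lat}, {self.lon})")
        if self.depth <= 0:
            raise ValueError("depth must be > 0 (metres below surface)")


@dataclass(frozen=True)
class TagDeployment:
    """A tagged fish's release event and tag duty-cycle parameters."""

    tag_id: str
    release_time: pd.Timestamp
    release_lat: float
    release_lon: float
    total_length: float            # cm
    min_interval: float = 30.0     # s, tag duty cycle lower bound
    max_interval: float = 120.0    # s, upper bound
    battery_days: float = 1400.0

    def __post_init__(self):
        if not self.tag_id:
            raise ValueError("tag_id must be non-empty")
        if not self.min_interval < self.max_interval:
            raise ValueError("min_interval must be < max_interval")
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")


@dataclass
class PolygonSet:
    """A named management/land geometry in WGS84 lon-lat."""

    name: str
    role: str
    geometry: MultiPolygon

    def __post_init__(self):
        if self.role not in POLYGON_ROLES:
            raise ValueError(f"unknown polygon role {self.role!r}; "
                             f"expected one of {sorted(POLYGON_ROLES)}")


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_detections(path, tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Read a detection log CSV.

    Returns a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``receiver_id``, ``tag_id``, sorted ascending by timestamp.  Rows whose
    timestamp cannot be parsed or whose identifiers are empty raise a
    ``ValueError`` reporting the offending line numbers (1-based, counting
    the header line).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, DETECTION_COLUMNS, "detections file")
    df = df[DETECTION_COLUMNS].copy()
    if df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        return df.reset_index(drop=True)

    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() | df["receiver_id"].isna() | df["tag_id"].isna() \
        | (df["receiver_id"].fillna("").str.strip() == "") \
        | (df["tag_id"].fillna("").str.strip() == "")
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 1-based
        shown = ", ".join(map(str, lines[:10]))
        raise ValueError(
            f"{int(bad.sum())} malformed detection row(s) at line(s) {shown}"
            + ("..." if len(lines) > 10 else "")
        )
    df["timestamp"] = ts
    df["receiver_id"] = df["receiver_id"].str.strip()
    df["tag_id"] = df["tag_id"].str.strip()
    # tz is not stored on the frame; local-day operations take it explicitly
    _ = tz
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def write_detections(dets: pd.DataFrame, path) -> None:
    out = dets[DETECTION_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_receivers(path) -> pd.DataFrame:
    """Read receiver metadata; validates coordinates and depth."""
    df = pd.read_csv(path)
    _require_columns(df, RECEIVER_COLUMNS, "receivers file")
    df = df[list(df.columns)].copy()
    df["receiver_id"] = df["receiver_id"].astype(str).str.strip()
    for col in ("lat", "lon", "depth"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError("receiver coordinates out of WGS84 range")
    if (df["depth"] <= 0).any():
        raise ValueError("receiver depth must be > 0 (metres below surface)")
    if df["in_kelp"].dtype != bool:
        df["in_kelp"] = df["in_kelp"].astype(str).str.strip().str.lower().isin(
            {"true", "1", "yes", "t"})
    return df.reset_index(drop=True)


def write_receivers(stations: pd.DataFrame, path) -> None:
    stations.to_csv(path, index=False)


def read_deployments(path) -> pd.DataFrame:
    """Read tag deployment metadata; validates duty cycle and lengths."""
    df = pd.read_csv(path)
    _require_columns(df, DEPLOYMENT_COLUMNS, "deployments file")
    df = df.copy()
    df["tag_id"] = df["tag_id"].astype(str).str.strip()
    df["release_time"] = pd.to_datetime(df["release_time"], utc=True, format="ISO8601")
    if (df["min_interval"] >= df["max_interval"]).any():
        raise ValueError("deployment min_interval must be < max_interval")
    if (df["total_length"] <= 0).any():
        raise ValueError("deployment total_length must be > 0")
    return df.reset_index(drop=True)


def write_deployments(deps: pd.DataFrame, path) -> None:
    out = deps.copy()
    out["release_time"] = out["release_time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def _local_date(ts: pd.Series, tz: str) -> pd.Series:
    return ts.dt.tz_convert(tz).dt.normalize()


def filter_tagging_day(dets: pd.DataFrame, deps: pd.DataFrame,
                       tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Drop detections logged on the local calendar date of the tag's release.

    Every tag present in ``dets`` must have a deployment row; unknown tags
    raise a ``ValueError`` listing them.  Detections of other tags on the
    same date are unaffected.
    """
    orphans = sorted(set(dets["tag_id"]) - set(deps["tag_id"]))
    if orphans:
        raise ValueError(f"detections reference unknown tag(s): {', '.join(orphans)}")
    if dets.empty:
        return dets.copy()
    release_date = deps.set_index("tag_id")["release_time"] \
        .dt.tz_convert(tz).dt.normalize()
    det_date = _local_date(dets["timestamp"], tz)
    drop = det_date.values == dets["tag_id"].map(release_date).values
    n_drop = int(np.sum(drop))
    if n_drop:
        logger.info("tagging-day filter removed %d detection(s)", n_drop)
    return dets.loc[~drop].reset_index(drop=True)


def filter_code_collisions(dets: pd.DataFrame, min_gap: float = 30.0) -> pd.DataFrame:
    """Drop implausibly close repeat detections within each (tag, receiver) stream.

    Scanning forward in time, a detection is dropped when it falls less
    than ``min_gap`` seconds after the last *retained* detection of the
    same tag on the same receiver; the earlier record of a too-close pair
    is always the one kept.  Applying the filter twice is a no-op.
    """
    if min_gap <= 0:
        raise ValueError("min_gap must be > 0 seconds")
    if dets.empty:
        return dets.copy()
    dets = dets.sort_values("timestamp", kind="stable")
    keep = np.ones(len(dets), dtype=bool)
    t_ns = dets["timestamp"].astype("int64").to_numpy()
    gap_ns = int(min_gap * 1e9)
    grouped = pd.Series(np.arange(len(dets))).groupby(
        [dets["tag_id"].to_numpy(), dets["receiver_id"].to_numpy()])
    for _, idx in grouped:
        pos = idx.to_numpy()
        last = t_ns[pos[0]]
        for p in pos[1:]:
            if t_ns[p] - last < gap_ns:
                keep[p] = False
            else:
                last = t_ns[p]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("collision filter removed %d detection(s) (< %.0f s gaps)",
                    n_drop, min_gap)
    return dets.loc[keep].reset_index(drop=True)


def _close_ring(ring, index):
    ring = [tuple(pt) for pt in ring]
    if ring[0] != ring[-1]:
        warnings.warn(f"feature {index}: unclosed ring auto-closed", stacklevel=2)
        ring.append(ring[0])
    return ring


def read_polygons(path) -> list[PolygonSet]:
    """Read a GeoJSON FeatureCollection of management/land polygons.

    Each feature must be a Polygon or MultiPolygon with a ``role``
    property.  Unclosed rings are closed with a warning; invalid (e.g.
    self-intersecting) geometries raise a ``ValueError`` naming the
    feature index.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("polygons file must be a GeoJSON FeatureCollection")
    out: list[PolygonSet] = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        role = props.get("role")
        if role is None:
            raise ValueError(f"feature {i} has no 'role' property")
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "Polygon":
            coords = [[_close_ring(r, i) for r in geom["coordinates"]]]
        elif gtype == "MultiPolygon":
            coords = [[_close_ring(r, i) for r in poly] for poly in geom["coordinates"]]
        else:
            raise ValueError(f"feature {i}: unsupported geometry type {gtype!r}")
        shp = shape({"type": "MultiPolygon", "coordinates": coords})
        if not shp.is_valid:
            raise ValueError(f"feature {i}: invalid geometry ({explain_validity(shp)})")
        out.append(PolygonSet(name=str(props.get("name", f"feature{i}")),
                              role=str(role), geometry=shp))
    return out


def write_polygons(polysets: list[PolygonSet], path) -> None:
    features = [
        {"type": "Feature",
         "properties": {"name": ps.name, "role": ps.role},
         "geometry": mapping(ps.geometry)}
        for ps in polysets
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def union_role(polysets: list[PolygonSet], roles) -> MultiPolygon:
    """Union of all geometries whose role is in ``roles`` (WGS84)."""
    from shapely.ops import unary_union

    if isinstance(roles, str):
        roles = {roles}
    geoms = [ps.geometry for ps in polysets if ps.role in roles]
    if not geoms:
        return MultiPolygon([])
    u = unary_union(geoms)
    if isinstance(u, Polygon):
        u = MultiPolygon([u])
    return u
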