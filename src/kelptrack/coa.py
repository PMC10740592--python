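"""Centers of activity, days at liberty, and residency indices.

A center of activity (COA) is a short-interval position estimate: within
each half-open time bin aligned to local midnight, the fish's position is
the detection-count-weighted mean of the coordinates of the receivers that
heard it.  Thirty-minute COAs feed the space-use analysis; ten-minute COAs
feed hourly movement rates.

Residency bookkeeping follows the tagging-study convention of civil local
days.  Study days at liberty count every calendar day from release to the
study end inclusive of the release date (the convention that reproduces
published tag summaries exactly); array days at liberty span first to last
detection inclusive; the residency indices divide distinct detection days
by each of those denominators, reported to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geo import project, unproject
from .io import DEFAULT_TZ

__all__ = [
    "ResidencySummary", "project_coordinates", "unproject_coordinates",
    "compute_coas", "days_at_liberty", "residency_indices",
    "residency_table", "detections_per_hour",
]


@dataclass
class ResidencySummary:
    """Per-fish residency metrics (one published-style summary row)."""

    tag_id: str
    station_count: int
    study_days_at_liberty: int
    array_days_at_liberty: int
    days_detected: int
    study_residency: float
    array_residency: float


def project_coordinates(lon, lat, origin):
    """Equirectangular projection of WGS84 degrees to local planar metres."""
    return project(lon, lat, origin)


def unproject_coordinates(x, y, origin):
    """Inverse of :func:`project_coordinates`."""
    return unproject(x, y, origin)


def _to_local_wall(ts: pd.Series, tz: str) -> pd.Series:
    """UTC timestamps -> naive local wall-clock times."""
    return ts.dt.tz_convert(tz).dt.tz_localize(None)


def compute_coas(dets: pd.DataFrame, stations: pd.DataFrame,
                 interval: float = 1800.0, tz: str = DEFAULT_TZ,
                 origin: tuple[float, float] | None = None) -> pd.DataFrame:
    """Bin detections into COAs on a local-midnight-aligned lattice.

    Parameters
    ----------
    dets : filtered detections (timestamp UTC, receiver_id, tag_id).
    stations : receiver table with lat/lon.
    interval : bin width in seconds (must divide 86400 to stay aligned
        to local midnight); 1800 for space use, 600 for movement rates.
    origin : projection origin (lon, lat); defaults to the station centroid.

    Returns a DataFrame with columns tag_id, interval_start (naive local
    wall time), x, y (projected metres), lat, lon, n_detections,
    n_receivers.  Intervals without detections emit nothing.
    """
    if interval <= 0:
        raise ValueError("interval must be > 0 seconds")
    if 86400 % int(interval):
        raise ValueError("interval must divide 86400 s to align with local midnight")
    if origin is None:
        origin = (float(stations["lon"].mean()), float(stations["lat"].mean()))
    unknown = sorted(set(dets["receiver_id"]) - set(stations["receiver_id"]))
    if unknown:
        raise ValueError(f"detections at unknown receiver(s): {', '.join(unknown)}")
    sx, sy = project(stations["lon"].to_numpy(), stations["lat"].to_numpy(), origin)
    coords = pd.DataFrame({"receiver_id": stations["receiver_id"],
                           "sx": sx, "sy": sy})
    if dets.empty:
        return pd.DataFrame(columns=["tag_id", "interval_start", "x", "y",
                                     "lat", "lon", "n_detections", "n_receivers"])
    d = dets.merge(coords, on="receiver_id", how="left")
    local = _to_local_wall(d["timestamp"], tz)
    d["interval_start"] = local.dt.floor(f"{int(interval)}s")
    grouped = d.groupby(["tag_id", "interval_start"], sort=True)
    out = grouped.agg(
        x=("sx", "mean"), y=("sy", "mean"),
        n_detections=("sx", "size"), n_receivers=("receiver_id", "nunique"),
    ).reset_index()
    lon, lat = unproject(out["x"].to_numpy(), out["y"].to_numpy(), origin)
    out["lat"] = lat
    out["lon"] = lon
    return out[["tag_id", "interval_start", "x", "y", "lat", "lon",
                "n_detections", "n_receivers"]]


def days_at_liberty(release_time: pd.Timestamp, study_end,
                    det_times: pd.Series | None = None,
                    tz: str = DEFAULT_TZ) -> tuple[int, int, int]:
    """(study_days, array_days, days_detected) in local calendar days.

    study_days counts release date through ``study_end`` inclusive;
    array_days counts first through last detection date inclusive (0 with
    no detections); days_detected counts distinct local dates with at
    least one detection.
    """
    release_date = pd.Timestamp(release_time).tz_convert(tz).date()
    study_end = pd.Timestamp(study_end).date()
    if study_end < release_date:
        raise ValueError("study_end precedes the release date")
    study_days = (study_end - release_date).days + 1
    if det_times is None or len(det_times) == 0:
        return study_days, 0, 0
    dates = det_times.dt.tz_convert(tz).dt.date
    array_days = (dates.max() - dates.min()).days + 1
    return study_days, array_days, int(dates.nunique())


def residency_indices(study_days: int, array_days: int,
                      days_detected: int) -> tuple[float, float]:
    """(study_residency, array_residency), rounded to three decimals."""
    if study_days <= 0:
        raise ValueError("study_days must be > 0")
    study = round(days_detected / study_days, 3)
    array = round(days_detected / array_days, 3) if array_days > 0 else 0.0
    return study, array


def residency_table(dets: pd.DataFrame, deps: pd.DataFrame, study_end,
                    tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Per-tag residency summary mirroring a published tagging table.

    One row per deployment (tags never detected get zero rows of activity),
    columns: tag_id, station_count, study_days_at_liberty,
    array_days_at_liberty, days_detected, study_residency, array_residency.
    """
    rows = []
    for dep in deps.itertuples(index=False):
        sub = dets[dets["tag_id"] == dep.tag_id]
        study, array, detected = days_at_liberty(
            dep.release_time, study_end, sub["timestamp"] if len(sub) else None, tz)
        sres, ares = residency_indices(study, array, detected)
        rows.append(ResidencySummary(
            tag_id=dep.tag_id, station_count=int(sub["receiver_id"].nunique()),
            study_days_at_liberty=study, array_days_at_liberty=array,
            days_detected=detected, study_residency=sres, array_residency=ares))
    return pd.DataFrame([vars(r) for r in rows])


def detections_per_hour(dets: pd.DataFrame, tag_id: str,
                        tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Hourly detection counts for one tag with a centred 12-h moving average.

    Hours between the first and last detection with no detections appear
    as explicit zeros.  Returns columns hour (naive local), n, ma12.
    """
    sub = dets[dets["tag_id"] == tag_id]
    if sub.empty:
        return pd.DataFrame(columns=["hour", "n", "ma12"])
    local = _to_local_wall(sub["timestamp"], tz)
    hours = local.dt.floor("h")
    counts = hours.value_counts().sort_index()
    full = pd.date_range(counts.index.min(), counts.index.max(), freq="h")
    counts = counts.reindex(full, fill_value=0)
    ma = counts.rolling(12, center=True, min_periods=1).mean()
    return pd.DataFrame({"hour": full, "n": counts.to_numpy(),
                         "ma12": ma.to_numpy()})
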