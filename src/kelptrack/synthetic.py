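"""Synthetic receiver arrays, fish tracks, transmissions, and detections.

Everything downstream — filtering, COAs, residency, range modelling,
space use, the hurdle model — is testable on data from this module, which
reproduces the statistical structure those analyses assume without
claiming behavioural realism:

* receivers on a (jittered) grid at a configurable spacing, with depths
  and kelp flags typical of a shallow coastal array;
* fish tracks as a discretised Ornstein–Uhlenbeck walk: mean reversion
  toward an activity centre gives a stationary home range, and the step
  SD is modulated by diel period and calendar month so that diel/seasonal
  activity signals propagate into realised movement rates;
* tag transmissions as a renewal process with i.i.d. uniform gaps (the
  randomized 30–120 s duty cycle of the tags being emulated);
* detections of each ping at each station as independent Bernoulli draws
  from a logistic distance model with a per-receiver random slope,
  matching the detection-range model's data-generating assumptions;
* mobile range-test drifts away from a mooring, recording per-ping
  detected/missed outcomes.

Defaults sit at the scale of the system being emulated: a 29-receiver
array at ~500 m spacing, detection parameters giving a global 50%-range
near 220 m with per-receiver spread of roughly 180–280 m, and
site-attached home ranges (stationary SD ~ 100 m) anchored near receiver
moorings — receivers are deployed on the reef features fish shelter at,
which is what makes real movement-rate data zero-inflated (long runs of
detections on a single receiver).  All generators are deterministic under a
fixed seed.  Simulation runs in planar metres about a single WGS84
origin; outputs use the CSV/GeoJSON dialects of :mod:`kelptrack.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .geo import project, unproject
from .io import DEFAULT_TZ, ReceiverStation

__all__ = [
    "MovementParams", "DetectionParams", "simulate_array", "simulate_track",
    "simulate_transmissions", "simulate_detections", "simulate_range_test",
    "make_scenario", "write_scenario",
]

LA_JOLLA_ORIGIN = (-117.27, 32.85)  # lon, lat


def _default_diel_multipliers() -> dict[str, float]:
    return {"dawn": 1.0, "day": 2.0, "dusk": 1.0, "night": 0.6}


def _default_monthly_multipliers() -> dict[int, float]:
    mult = {m: 1.0 for m in range(1, 13)}
    mult.update({5: 1.3, 6: 1.5, 7: 1.6, 8: 1.1})  # summer-elevated activity
    return mult


@dataclass
class MovementParams:
    """Mean-reverting (OU) track parameters.

    ``step_sd`` is the diffusive scale in m per sqrt(second); the
    stationary home-range SD of the walk is step_sd / sqrt(2 * kappa)
    with kappa = attraction / 3600 per second.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    attraction: float = 0.3          # per hour, mean reversion rate
    step_sd: float = 1.2             # m / sqrt(s); stationary SD ~ 93 m
    dt: float = 60.0                 # s per step
    diel_speed_multiplier: Mapping[str, float] = field(
        default_factory=_default_diel_multipliers)
    monthly_speed_multiplier: Mapping[int, float] = field(
        default_factory=_default_monthly_multipliers)
    emigration_time: pd.Timestamp | None = None
    ref_lat: float = LA_JOLLA_ORIGIN[1]
    ref_lon: float = LA_JOLLA_ORIGIN[0]
    tz: str = DEFAULT_TZ
    seed: int = 0

    def __post_init__(self):
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.attraction < 0:
            raise ValueError("attraction must be >= 0")
        if any(v <= 0 for v in self.diel_speed_multiplier.values()) or \
                any(v <= 0 for v in self.monthly_speed_multiplier.values()):
            raise ValueError("speed multipliers must be positive")


@dataclass
class DetectionParams:
    """Logistic distance-detection parameters (logit scale)."""

    beta0: float = 9.0               # intercept; p(0 m) ~ 1
    beta1: float = -0.0412           # slope per metre; global d50 ~ 218 m
    receiver_slope_sd: float = 0.005  # per-receiver slope SD
    seed: int = 0

    def __post_init__(self):
        if self.beta1 >= 0:
            raise ValueError("beta1 must be negative")
        if self.receiver_slope_sd < 0:
            raise ValueError("receiver_slope_sd must be >= 0")


def simulate_array(n_receivers: int = 29, spacing: float = 500.0,
                   layout: str = "jittered-grid",
                   origin: tuple[float, float] = LA_JOLLA_ORIGIN,
                   seed: int = 0, depth_range: tuple[float, float] = (11.0, 25.0),
                   kelp_fraction: float = 0.7) -> pd.DataFrame:
    """Receiver stations on a (jittered) grid centred on ``origin``.

    Returns a station table with lat/lon plus planar x/y columns (metres
    relative to ``origin``).  Jitter is uniform within ±20% of the spacing.
    """
    if n_receivers < 1:
        raise ValueError("n_receivers must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if layout not in {"grid", "jittered-grid"}:
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_receivers)))
    idx = np.arange(n_receivers)
    col = idx % ncols
    row = idx // ncols
    nrows = row.max() + 1
    x = (col - (ncols - 1) / 2.0) * spacing
    y = (row - (nrows - 1) / 2.0) * spacing
    if layout == "jittered-grid":
        x = x + rng.uniform(-0.2, 0.2, n_receivers) * spacing
        y = y + rng.uniform(-0.2, 0.2, n_receivers) * spacing
    lon, lat = unproject(x, y, origin)
    return pd.DataFrame({
        "receiver_id": [f"R{i + 1:02d}" for i in idx],
        "lat": lat, "lon": lon,
        "depth": rng.uniform(*depth_range, n_receivers).round(2),
        "in_kelp": rng.random(n_receivers) < kelp_fraction,
        "x": x, "y": y,
    })


def simulate_track(p: MovementParams, t0: pd.Timestamp,
                   t1: pd.Timestamp) -> pd.DataFrame:
    """Discrete OU walk from ``t0`` to ``t1`` at step ``p.dt`` seconds.

    Each step:  delta = -kappa (pos - center) dt + s sqrt(dt) eps,
    with the step SD ``s`` scaled by the diel and monthly multipliers of
    the step's local time.  Truncated at ``p.emigration_time`` if set.
    Returns columns t (UTC), x, y.
    """
    from .movement import diel_period_series

    t0 = pd.Timestamp(t0)
    t1 = pd.Timestamp(t1)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    if t1.tzinfo is None:
        t1 = t1.tz_localize("UTC")
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    n_steps = int(np.floor((t1 - t0).total_seconds() / p.dt))
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * p.dt, unit="s")
    if p.emigration_time is not None:
        emi = pd.Timestamp(p.emigration_time)
        if emi.tzinfo is None:
            emi = emi.tz_localize("UTC")
        times = times[times <= emi]
    n = len(times)
    if n == 0:
        return pd.DataFrame(columns=["t", "x", "y"])

    diel = diel_period_series(pd.Series(times), p.ref_lat, p.ref_lon, p.tz)
    months = pd.Series(times).dt.tz_convert(p.tz).dt.month
    scale = (np.array([p.diel_speed_multiplier.get(d, 1.0) for d in diel])
             * np.array([p.monthly_speed_multiplier.get(m, 1.0) for m in months]))

    rng = np.random.default_rng(p.seed)
    eps = rng.standard_normal((n, 2))
    kappa = p.attraction / 3600.0
    sqdt = np.sqrt(p.dt)
    pos = np.empty((n, 2))
    pos[0] = (p.center_x, p.center_y)
    center = np.array([p.center_x, p.center_y])
    for i in range(1, n):
        s = p.step_sd * scale[i - 1]
        pos[i] = (pos[i - 1]
                  - kappa * (pos[i - 1] - center) * p.dt
                  + s * sqdt * eps[i - 1])
    return pd.DataFrame({"t": times, "x": pos[:, 0], "y": pos[:, 1]})


def simulate_transmissions(track: pd.DataFrame, min_interval: float = 30.0,
                           max_interval: float = 120.0,
                           seed: int = 0) -> pd.DataFrame:
    """Tag pings along a track: i.i.d. uniform gaps, positions interpolated.

    The first ping occurs one gap after the track start (renewal process).
    Returns columns t, x, y; empty for an empty or instantaneous track.
    """
    if not min_interval < max_interval and min_interval != max_interval:
        raise ValueError("min_interval must be <= max_interval")
    if len(track) < 2:
        return pd.DataFrame(columns=["t", "x", "y"])
    rng = np.random.default_rng(seed)
    t_s = track["t"].astype("int64").to_numpy() / 1e9
    duration = t_s[-1] - t_s[0]
    n_max = int(duration / min_interval) + 2
    gaps = rng.uniform(min_interval, max_interval, n_max)
    ping_s = t_s[0] + np.cumsum(gaps)
    ping_s = ping_s[ping_s <= t_s[-1]]
    x = np.interp(ping_s, t_s, track["x"].to_numpy())
    y = np.interp(ping_s, t_s, track["y"].to_numpy())
    t = pd.to_datetime((ping_s * 1e9).astype("int64"), utc=True)
    return pd.DataFrame({"t": t, "x": x, "y": y})


def simulate_detections(pings: pd.DataFrame, stations: pd.DataFrame,
                        dp: DetectionParams, tag_id: str = "T1",
                        origin: tuple[float, float] = LA_JOLLA_ORIGIN) -> pd.DataFrame:
    """Bernoulli detection of each ping at each station.

    Detection probability is expit(beta0 + (beta1 + b_j) * d) with d the
    planar ping-station distance and b_j a per-station slope deviation
    drawn once from N(0, receiver_slope_sd²).  Returns a detections table
    (timestamp, receiver_id, tag_id) sorted by time.
    """
    from scipy.special import expit

    if stations.empty:
        raise ValueError("stations must be non-empty")
    if {"x", "y"}.issubset(stations.columns):
        sx = stations["x"].to_numpy(float)
        sy = stations["y"].to_numpy(float)
    else:
        sx, sy = project(stations["lon"].to_numpy(), stations["lat"].to_numpy(),
                         origin)
    if pings.empty:
        return pd.DataFrame(columns=["timestamp", "receiver_id", "tag_id"])
    rng = np.random.default_rng(dp.seed)
    b = rng.normal(0.0, dp.receiver_slope_sd, len(stations))
    dx = pings["x"].to_numpy()[:, None] - sx[None, :]
    dy = pings["y"].to_numpy()[:, None] - sy[None, :]
    dist = np.hypot(dx, dy)
    prob = expit(dp.beta0 + (dp.beta1 + b[None, :]) * dist)
    hit = rng.random(prob.shape) < prob
    ip, js = np.nonzero(hit)
    out = pd.DataFrame({
        "timestamp": pings["t"].to_numpy()[ip],
        "receiver_id": stations["receiver_id"].to_numpy()[js],
        "tag_id": tag_id,
    })
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def simulate_range_test(station: ReceiverStation, drift_speed: float,
                        heading: float, dp: DetectionParams,
                        duration: float, seed: int = 0,
                        min_interval: float = 30.0,
                        max_interval: float = 120.0,
                        t0: pd.Timestamp | str = "2021-06-01 17:00:00+00:00"
                        ) -> pd.DataFrame:
    """A mobile range-test drift away from a mooring.

    The mobile unit starts at the mooring and drifts at ``drift_speed``
    m/s along ``heading`` degrees (clockwise from north); the towed tag
    pings with uniform gaps and each ping is detected by the moored
    receiver with the logistic distance probability (per-receiver slope
    deviation drawn from the detection seed).  Returns per-ping rows
    (timestamp, lat, lon, receiver_id, detected).
    """
    from scipy.special import expit

    if drift_speed <= 0:
        raise ValueError("drift_speed must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n_max = int(duration / min_interval) + 2
    gaps = rng.uniform(min_interval, max_interval, n_max)
    t_rel = np.cumsum(gaps)
    t_rel = t_rel[t_rel <= duration]
    head = np.radians(heading)
    x = drift_speed * t_rel * np.sin(head)
    y = drift_speed * t_rel * np.cos(head)
    origin = (station.lon, station.lat)
    lon, lat = unproject(x, y, origin)
    dist = drift_speed * t_rel
    b_j = np.random.default_rng(dp.seed).normal(0.0, dp.receiver_slope_sd)
    prob = expit(dp.beta0 + (dp.beta1 + b_j) * dist)
    detected = (rng.random(len(t_rel)) < prob).astype(int)
    t0 = pd.Timestamp(t0)
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    return pd.DataFrame({
        "timestamp": t0 + pd.to_timedelta(t_rel, unit="s"),
        "lat": lat, "lon": lon,
        "receiver_id": station.receiver_id,
        "detected": detected,
    })


def make_scenario(seed: int = 0, n_fish: int = 3, n_receivers: int = 29,
                  spacing: float = 500.0, days: float = 10.0,
                  start: str = "2021-03-01 08:00:00+00:00",
                  dp: DetectionParams | None = None,
                  movement_kw: dict | None = None,
                  n_range_receivers: int = 3,
                  origin: tuple[float, float] = LA_JOLLA_ORIGIN) -> dict:
    """A complete synthetic study: array, fish, detections, range drifts, zones.

    Returns a dict with keys ``stations``, ``deployments``, ``detections``,
    ``rangetest`` (DataFrames), ``polygons`` (list of PolygonSet), ``origin``
    and ``tracks`` (per-fish position series, for ground-truth checks).
    Fish are released near distinct activity centres inside the array and
    wander as OU walks; detection and movement parameters default to the
    module-level scales.
    """
    from shapely.geometry import MultiPolygon, box as shp_box

    from .geo import unproject_geometry
    from .io import PolygonSet

    rng = np.random.default_rng(seed)
    dp = dp or DetectionParams(seed=int(rng.integers(2**31)))
    stations = simulate_array(n_receivers=n_receivers, spacing=spacing,
                              origin=origin, seed=int(rng.integers(2**31)))
    half_w = (stations["x"].max() - stations["x"].min()) / 2.0
    half_h = (stations["y"].max() - stations["y"].min()) / 2.0
    t0 = pd.Timestamp(start)
    t1 = t0 + pd.Timedelta(days=days)

    deployments, detections, tracks = [], [], {}
    for k in range(n_fish):
        tag = f"T{k + 1:02d}"
        # activity centres sit near receiver moorings: receivers are placed
        # on the reef features fish hold on
        j = int(rng.integers(len(stations)))
        center = (float(stations["x"].iloc[j]) + rng.normal(0.0, 40.0),
                  float(stations["y"].iloc[j]) + rng.normal(0.0, 40.0))
        mp_kw = dict(center_x=center[0], center_y=center[1],
                     seed=int(rng.integers(2**31)))
        mp_kw.update(movement_kw or {})
        mp = MovementParams(**mp_kw)
        track = simulate_track(mp, t0, t1)
        tracks[tag] = track
        pings = simulate_transmissions(track, seed=int(rng.integers(2**31)))
        dets = simulate_detections(
            pings, stations,
            DetectionParams(beta0=dp.beta0, beta1=dp.beta1,
                            receiver_slope_sd=dp.receiver_slope_sd,
                            seed=dp.seed),
            tag_id=tag, origin=origin)
        detections.append(dets)
        rel_lon, rel_lat = unproject(center[0], center[1], origin)
        deployments.append({
            "tag_id": tag, "release_time": t0, "release_lat": float(rel_lat),
            "release_lon": float(rel_lon),
            "total_length": float(np.round(rng.uniform(77, 163), 1)),
            "min_interval": 30.0, "max_interval": 120.0, "battery_days": 1400.0,
        })
    detections = pd.concat(detections, ignore_index=True) \
        .sort_values("timestamp", kind="stable").reset_index(drop=True)
    deployments = pd.DataFrame(deployments)

    rangetest = []
    for j in range(min(n_range_receivers, len(stations))):
        st = stations.iloc[j]
        station = ReceiverStation(receiver_id=st["receiver_id"],
                                  lat=float(st["lat"]), lon=float(st["lon"]),
                                  depth=float(st["depth"]),
                                  in_kelp=bool(st["in_kelp"]))
        drift = simulate_range_test(
            station, drift_speed=0.15, heading=float(rng.uniform(0, 360)),
            dp=dp, duration=3600.0, seed=int(rng.integers(2**31)),
            min_interval=8.0, max_interval=12.0, t0=t0)
        rangetest.append(drift)
    rangetest = pd.concat(rangetest, ignore_index=True)

    # one no-take zone over the western half of the array, land to the east
    mpa_planar = shp_box(-half_w - spacing, -half_h - spacing, 0.0,
                         half_h + spacing)
    land_planar = shp_box(half_w + 2 * spacing, -half_h - 2 * spacing,
                          half_w + 10 * spacing, half_h + 2 * spacing)
    polygons = [
        PolygonSet(name="reserve", role="mpa_no_take",
                   geometry=MultiPolygon([unproject_geometry(mpa_planar, origin)])),
        PolygonSet(name="shore", role="land",
                   geometry=MultiPolygon([unproject_geometry(land_planar, origin)])),
    ]
    return {"stations": stations, "deployments": deployments,
            "detections": detections, "rangetest": rangetest,
            "polygons": polygons, "origin": origin, "tracks": tracks,
            "study_end": t1.date()}


def write_scenario(scenario: dict, outdir) -> dict:
    """Write a scenario to the standard CSV/GeoJSON files; returns the paths."""
    import pathlib

    from . import io as kio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": outdir / "detections.csv",
        "receivers": outdir / "receivers.csv",
        "deployments": outdir / "deployments.csv",
        "rangetest": outdir / "rangetest.csv",
        "polygons": outdir / "polygons.geojson",
    }
    kio.write_detections(scenario["detections"], paths["detections"])
    kio.write_receivers(
        scenario["stations"].drop(columns=[c for c in ("x", "y")
                                           if c in scenario["stations"]]),
        paths["receivers"])
    kio.write_deployments(scenario["deployments"], paths["deployments"])
    rt = scenario["rangetest"].copy()
    rt["timestamp"] = rt["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    rt.to_csv(paths["rangetest"], index=False)
    kio.write_polygons(scenario["polygons"], paths["polygons"])
    return paths
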