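"""Config-driven orchestration of the full telemetry analysis.

Stages: read + filter detections -> residency table -> detection-range
fit -> 30-min COAs -> seasonal KUDs with land clipping and MPA overlap ->
10-min COAs -> hourly movement rates -> hurdle model.  Every stage output
is written as a plain re-loadable artifact, so the pipeline can be
restarted from any intermediate file, and the run is deterministic given
the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import yaml

from . import coa, io, movement, range_model, space_use
from .geo import project_geometry
from .io import DEFAULT_TZ, ReceiverStation

logger = logging.getLogger(__name__)

MIN_COAS_FOR_KUD = 5  # fewer points give a meaningless kernel estimate


@dataclasses.dataclass
class RunConfig:
    """All inputs and tunables of one analysis run."""

    detections: str
    receivers: str
    deployments: str
    study_end: str                       # ISO date
    rangetest: str | None = None
    polygons: str | None = None
    timezone: str = DEFAULT_TZ
    min_gap: float = 30.0                # collision filter, seconds
    coa_interval_kud: int = 1800
    coa_interval_rate: int = 600
    spawning_months: tuple = tuple(range(5, 11))
    kud_cell_size: float = 25.0
    kud_levels: tuple = (0.5, 0.95)

    def __post_init__(self):
        for name in ("coa_interval_kud", "coa_interval_rate"):
            if 3600 % int(getattr(self, name)):
                raise ValueError(f"{name} must divide 3600 s")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns a dict with the in-memory stage results.  Raises with the
    stage name on any failure.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load-inputs"
    try:
        dets = io.read_detections(cfg.detections, tz=cfg.timezone)
        stations = io.read_receivers(cfg.receivers)
        deps = io.read_deployments(cfg.deployments)
        release_dates = deps["release_time"].dt.tz_convert(cfg.timezone).dt.date
        if (release_dates > np.datetime64(cfg.study_end).astype(object)).any():
            raise ValueError("study_end precedes at least one release date")

        stage = "filter"
        n0 = len(dets)
        dets = io.filter_tagging_day(dets, deps, tz=cfg.timezone)
        n1 = len(dets)
        dets = io.filter_code_collisions(dets, min_gap=cfg.min_gap)
        n2 = len(dets)
        logger.info("filtering: %d raw, %d after tagging-day, %d after collision",
                    n0, n1, n2)
        results["filter_counts"] = {"raw": n0, "after_tagging_day": n1,
                                    "after_collision": n2}
        io.write_detections(dets, outdir / "detections_filtered.csv")

        stage = "residency"
        res_table = coa.residency_table(dets, deps, cfg.study_end, tz=cfg.timezone)
        res_table.to_csv(outdir / "residency.csv", index=False)
        results["residency"] = res_table

        stage = "range-fit"
        if cfg.rangetest:
            import pandas as pd

            rt = pd.read_csv(cfg.rangetest)
            rt["timestamp"] = pd.to_datetime(rt["timestamp"], utc=True,
                                             format="ISO8601")
            obs = []
            for rid, grp in rt.groupby("receiver_id"):
                st = stations[stations["receiver_id"] == rid].iloc[0]
                station = ReceiverStation(
                    receiver_id=rid, lat=float(st["lat"]), lon=float(st["lon"]),
                    depth=float(st["depth"]), in_kelp=bool(st["in_kelp"]))
                obs.append(range_model.build_range_observations(grp, station))
            obs = pd.concat(obs, ignore_index=True)
            fit = range_model.fit_detection_glmm(obs)
            report = {
                "beta0": fit.beta0, "beta1": fit.beta1,
                "slope_sd": fit.slope_sd, "converged": fit.converged,
                "d50_global_m": range_model.d50(fit),
                "d50_per_receiver_m": {
                    r: range_model.d50(fit, r) for r in fit.b},
                "n_obs": fit.n_obs, "n_receivers": fit.n_receivers,
            }
            with open(outdir / "range_fit.json", "w") as fh:
                json.dump(report, fh, indent=2)
            results["range_fit"] = fit

        stage = "coa"
        origin = (float(stations["lon"].mean()), float(stations["lat"].mean()))
        coas30 = coa.compute_coas(dets, stations, interval=cfg.coa_interval_kud,
                                  tz=cfg.timezone, origin=origin)
        coas30.to_csv(outdir / "coas_kud.csv", index=False)
        results["coas_kud"] = coas30

        stage = "space-use"
        land = mpas = None
        if cfg.polygons:
            polysets = io.read_polygons(cfg.polygons)
            land_wgs = io.union_role(polysets, "land")
            mpa_wgs = io.union_role(polysets, {"mpa_no_take", "conservation_area"})
            land = project_geometry(land_wgs, origin) if not land_wgs.is_empty else None
            mpas = project_geometry(mpa_wgs, origin) if not mpa_wgs.is_empty else None
        overlap_rows = []
        for tag, tag_coas in coas30.groupby("tag_id"):
            spawn, nonspawn = space_use.split_by_season(
                tag_coas, set(cfg.spawning_months))
            for season, sub in (("spawning", spawn), ("non_spawning", nonspawn)):
                pts = sub[["x", "y"]].to_numpy()
                if len(pts) < MIN_COAS_FOR_KUD or np.all(pts.std(axis=0) == 0):
                    logger.info("skipping KUD for %s/%s (n=%d)", tag, season,
                                len(pts))
                    continue
                h = space_use.href_bandwidth(pts)
                grid = space_use.kud(pts, h, cell_size=cfg.kud_cell_size,
                                     season=season)
                for level in cfg.kud_levels:
                    contour = space_use.volume_contour(grid, level)
                    if land is not None:
                        contour = space_use.clip_to_sea(contour, land)
                    if mpas is not None:
                        _, frac = space_use.overlap_with_polygons(contour, mpas)
                    else:
                        frac = float("nan")
                    overlap_rows.append({
                        "tag_id": tag, "season": season, "level": level,
                        "n_coas": len(pts), "bandwidth_m": h,
                        "area_km2": contour.area_km2, "mpa_fraction": frac})
        import pandas as pd

        overlap = pd.DataFrame(overlap_rows)
        overlap.to_csv(outdir / "kud_overlap.csv", index=False)
        results["kud_overlap"] = overlap

        stage = "movement-rates"
        coas10 = coa.compute_coas(dets, stations, interval=cfg.coa_interval_rate,
                                  tz=cfg.timezone, origin=origin)
        rates = movement.hourly_movement_rates(
            coas10, lat=origin[1], lon=origin[0], tz=cfg.timezone)
        rates.to_csv(outdir / "movement_rates.csv", index=False)
        results["movement_rates"] = rates

        stage = "hurdle"
        if (len(rates) and rates["tag_id"].nunique() >= 2
                and rates["moved"].nunique() == 2
                and (rates["rate"] > 0).sum() >= 10):
            include_month = rates["month"].nunique() > 1
            hurdle = movement.fit_hurdle(rates, include_month=include_month)
            with open(outdir / "hurdle.txt", "w") as fh:
                fh.write(movement.format_hurdle_report(hurdle))
            with open(outdir / "hurdle.json", "w") as fh:
                json.dump({
                    "binary": {"params": dict(zip(hurdle.binary.names,
                                                  hurdle.binary.params.tolist())),
                               "sigma_alpha": hurdle.binary.sigma,
                               "r2_marginal": hurdle.r2_binary[0],
                               "r2_conditional": hurdle.r2_binary[1]},
                    "positive": {"params": dict(zip(hurdle.positive.names,
                                                    hurdle.positive.params.tolist())),
                                 "sigma_alpha": hurdle.positive.sigma_alpha,
                                 "sigma_e": hurdle.positive.sigma_e,
                                 "r2_marginal": hurdle.r2_positive[0],
                                 "r2_conditional": hurdle.r2_positive[1]},
                }, fh, indent=2)
            results["hurdle"] = hurdle
        else:
            logger.info("hurdle model skipped: insufficient movement-rate data")

        stage = "report"
        cfg_dict = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(cfg).items()}
        with open(outdir / "run_config.yml", "w") as fh:
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
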