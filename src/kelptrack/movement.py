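"""Hourly movement rates and the two-part (hurdle) movement model.

Movement rates come from ten-minute COAs: an hour contributes a record
only when all six of its ten-minute bins produced a COA, and the rate is
the sum of the five consecutive inter-COA distances (metres per hour).  A
rate of exactly zero — every COA at the same single receiver — is common
in array data, so the rates are modelled in two parts:

* binary part: logit P(rate > 0) ~ diel + lunar + month + (1 | individual),
  a logistic mixed model fit by Laplace maximum likelihood;
* positive part: rate | rate > 0 ~ same covariates, a linear mixed model
  fit by REML.

Covariates are derived, never supplied: diel period from NOAA solar
events (dawn = [civil dawn, sunrise + 1 h), day = [sunrise + 1 h,
sunset − 1 h), dusk = [sunset − 1 h, civil dusk), night = the rest),
lunar phase from the mean synodic cycle (29.530588 d anchored at the
2000-01-06 18:14 UTC new moon, quartered with new centred on 0° and full
on 180°), and month of the local hour.  Reference levels are dawn, new
moon, and January.  Inference is by Wald tests against a normal
reference.  Pseudo-R² values (marginal and conditional) use the
delta-method observation-level variance: sigma_e² for the linear part and
1 / (p̄ (1 − p̄)) for the logit part, with p̄ the mean fitted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import solar
from .glmm import LogisticMixedFit, fit_logistic_mixed
from .io import DEFAULT_TZ

__all__ = [
    "DIEL_LEVELS", "LUNAR_LEVELS", "HurdleFit", "PositivePartFit",
    "diel_period", "lunar_phase", "hourly_movement_rates", "build_design",
    "fit_binary_part", "fit_positive_part", "pseudo_r2", "fit_hurdle",
]

DIEL_LEVELS = ["dawn", "day", "dusk", "night"]
LUNAR_LEVELS = ["new", "waxing", "full", "waning"]

SYNODIC_DAYS = 29.530588
NEW_MOON_EPOCH = pd.Timestamp("2000-01-06 18:14:00", tz="UTC")


def _sun_windows(date, lat, lon, buffer_h: float = 1.0):
    ev = solar.sun_events_utc(date, lat, lon)
    buf = pd.Timedelta(hours=buffer_h)
    return (ev["civil_dawn"], ev["sunrise"] + buf,
            ev["sunset"] - buf, ev["civil_dusk"])


def diel_period(t: pd.Timestamp, lat: float, lon: float,
                tz: str = DEFAULT_TZ, buffer_h: float = 1.0) -> str:
    """Classify an instant as dawn, day, dusk, or night."""
    t = pd.Timestamp(t)
    if t.tzinfo is None:
        t = t.tz_localize(tz)
    t = t.tz_convert("UTC")
    local_date = t.tz_convert(tz).date()
    dawn0, day0, dusk0, night0 = _sun_windows(local_date, lat, lon, buffer_h)
    if dawn0 <= t < day0:
        return "dawn"
    if day0 <= t < dusk0:
        return "day"
    if dusk0 <= t < night0:
        return "dusk"
    return "night"


def diel_period_series(times: pd.Series, lat: float, lon: float,
                       tz: str = DEFAULT_TZ, buffer_h: float = 1.0) -> pd.Series:
    """Vectorised :func:`diel_period`; solar events computed once per date."""
    t = pd.Series(pd.to_datetime(times))
    if t.dt.tz is None:
        t = t.dt.tz_localize(tz, ambiguous=True, nonexistent="shift_forward")
    t_utc = t.dt.tz_convert("UTC")
    dates = t_utc.dt.tz_convert(tz).dt.date
    out = pd.Series("night", index=t.index, dtype=object)
    for date in pd.unique(dates):
        dawn0, day0, dusk0, night0 = _sun_windows(date, lat, lon, buffer_h)
        sel = (dates == date).to_numpy()
        tt = t_utc[sel]
        lab = np.full(sel.sum(), "night", dtype=object)
        lab[(tt >= dawn0) & (tt < day0)] = "dawn"
        lab[(tt >= day0) & (tt < dusk0)] = "day"
        lab[(tt >= dusk0) & (tt < night0)] = "dusk"
        out.iloc[np.nonzero(sel)[0]] = lab
    return out


def lunar_phase(t: pd.Timestamp, tz: str = DEFAULT_TZ) -> str:
    """Lunar phase category from the mean synodic cycle."""
    return lunar_phase_series(pd.Series([pd.Timestamp(t)]), tz).iloc[0]


def lunar_phase_series(times: pd.Series, tz: str = DEFAULT_TZ) -> pd.Series:
    t = pd.Series(pd.to_datetime(times))
    if t.dt.tz is None:
        t = t.dt.tz_localize(tz, ambiguous=True, nonexistent="shift_forward")
    age_days = (t.dt.tz_convert("UTC") - NEW_MOON_EPOCH).dt.total_seconds() / 86400.0
    theta = (age_days / SYNODIC_DAYS % 1.0) * 360.0
    out = pd.Series("new", index=t.index, dtype=object)
    out[(theta >= 45) & (theta < 135)] = "waxing"
    out[(theta >= 135) & (theta < 225)] = "full"
    out[(theta >= 225) & (theta < 315)] = "waning"
    return out


def hourly_movement_rates(coas_10min: pd.DataFrame, lat: float, lon: float,
                          tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Hourly movement rates from ten-minute COAs, with derived covariates.

    Only clock hours whose six ten-minute bins each have a COA for the tag
    contribute; the rate sums the five consecutive Euclidean inter-COA
    distances.  Covariates (diel, lunar, month) are evaluated at the hour
    midpoint.  Returns columns tag_id, hour_start (naive local), rate,
    moved, diel, lunar, month.
    """
    cols = ["tag_id", "hour_start", "rate", "moved", "diel", "lunar", "month"]
    if coas_10min.empty:
        return pd.DataFrame(columns=cols)
    c = coas_10min.sort_values(["tag_id", "interval_start"]).copy()
    c["hour_start"] = c["interval_start"].dt.floor("h")
    rows = []
    for (tag, hour), grp in c.groupby(["tag_id", "hour_start"], sort=True):
        if len(grp) != 6:
            continue
        xy = grp[["x", "y"]].to_numpy()
        rate = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        rows.append((tag, hour, rate))
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows, columns=["tag_id", "hour_start", "rate"])
    out["moved"] = (out["rate"] > 0).astype(int)
    mid = out["hour_start"] + pd.Timedelta(minutes=30)
    out["diel"] = diel_period_series(mid, lat, lon, tz).to_numpy()
    out["lunar"] = lunar_phase_series(mid, tz).to_numpy()
    out["month"] = out["hour_start"].dt.month
    return out[cols]


def build_design(records: pd.DataFrame, include_diel: bool = True,
                 include_lunar: bool = True, include_month: bool = True):
    """Treatment-contrast design matrix (references: dawn, new, January).

    Returns (X, names).  Factor levels absent from the data simply drop
    their column, keeping the matrix full rank.
    """
    n = len(records)
    cols = [np.ones(n)]
    names = ["(Intercept)"]

    def add_factor(column, ordered_levels, label):
        present = [lev for lev in ordered_levels
                   if (records[column] == lev).any()]
        # reference is the conventional first level, or the first present
        # one if the convention is absent from the data
        for lev in present[1:] if ordered_levels[0] not in present else \
                [lv for lv in present if lv != ordered_levels[0]]:
            cols.append((records[column] == lev).to_numpy(float))
            names.append(f"{label}[{lev}]")

    if include_diel:
        add_factor("diel", DIEL_LEVELS, "diel")
    if include_lunar:
        add_factor("lunar", LUNAR_LEVELS, "lunar")
    if include_month:
        add_factor("month", list(range(1, 13)), "month")
    return np.column_stack(cols), names


def fit_binary_part(records: pd.DataFrame, **design_kw) -> LogisticMixedFit:
    """Binomial GLMM for P(moved): Laplace ML with a per-individual intercept."""
    if records["tag_id"].nunique() < 2:
        raise ValueError("binary part needs at least two individuals")
    X, names = build_design(records, **design_kw)
    y = records["moved"].to_numpy(float)
    for col in ("diel", "lunar", "month"):
        if col in records:
            level_means = records.groupby(col)["moved"].mean()
            degenerate = level_means[(level_means == 0) | (level_means == 1)]
            for lev in degenerate.index:
                warnings.warn(f"{col} level {lev!r} has all-"
                              f"{int(level_means[lev])} outcomes (separation risk)",
                              stacklevel=2)
    return fit_logistic_mixed(X, y, records["tag_id"].to_numpy(), z=None,
                              names=names)


@dataclass
class PositivePartFit:
    """REML linear mixed fit of the non-zero movement rates."""

    params: np.ndarray
    names: list[str]
    se: np.ndarray
    sigma_alpha: float       # random-intercept SD
    sigma_e: float           # residual SD
    ranef: dict
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    linpred_fixed: np.ndarray

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.tvalues))


def fit_positive_part(records: pd.DataFrame, **design_kw) -> PositivePartFit:
    """LMM (REML) for rates given movement, random intercept per individual."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    pos = records[records["rate"] > 0]
    if pos.empty:
        raise ValueError("no positive movement rates")
    if pos["tag_id"].nunique() < 2:
        raise ValueError("positive part needs at least two individuals")
    X, names = build_design(pos, **design_kw)
    y = pos["rate"].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=pos["tag_id"].to_numpy())
        # powell is robust when the variance component sits on the boundary;
        # gradient methods there can stall on a singular profile solve
        res = model.fit(reml=True, method="powell")
    var_alpha = float(np.asarray(res.cov_re).ravel()[0])
    boundary = var_alpha <= 1e-10
    if boundary:
        warnings.warn("random-intercept variance at boundary (sigma_alpha = 0)",
                      stacklevel=2)
        var_alpha = max(var_alpha, 0.0)
    fe = np.asarray(res.fe_params, dtype=float)
    if boundary:
        ranef = {g: 0.0 for g in pos["tag_id"].unique()}
        se = np.sqrt(np.abs(np.diag(res.cov_params()))[:len(fe)])
    else:
        ranef = {g: float(np.asarray(v).ravel()[0])
                 for g, v in res.random_effects.items()}
        se = np.asarray(res.bse_fe, dtype=float)
    return PositivePartFit(
        params=fe, names=names, se=se,
        sigma_alpha=float(np.sqrt(var_alpha)), sigma_e=float(np.sqrt(res.scale)),
        ranef=ranef,
        loglik=float(res.llf), converged=bool(res.converged),
        n_obs=len(pos), n_groups=pos["tag_id"].nunique(),
        linpred_fixed=X @ fe)


def pseudo_r2(fit) -> tuple[float, float]:
    """(marginal, conditional) pseudo-R² by the variance-partition method.

    marginal    = var_f / (var_f + var_alpha + var_d)
    conditional = (var_f + var_alpha) / (var_f + var_alpha + var_d)

    var_f is the variance of the fixed-effect linear predictor over the
    data; var_d is sigma_e² for a linear fit and the delta-method logit
    observation variance 1 / (p̄ (1 − p̄)) for a binary fit.
    """
    var_f = float(np.var(fit.linpred_fixed, ddof=1)) \
        if len(fit.linpred_fixed) > 1 else 0.0
    if isinstance(fit, PositivePartFit):
        var_alpha = fit.sigma_alpha ** 2
        var_d = fit.sigma_e ** 2
    else:
        var_alpha = fit.sigma ** 2
        pbar = float(np.mean(expit(fit.linpred_full)))
        var_d = 1.0 / (pbar * (1.0 - pbar))
    denom = var_f + var_alpha + var_d
    return var_f / denom, (var_f + var_alpha) / denom


@dataclass
class HurdleFit:
    """Paired binary/positive fits with their pseudo-R² values."""

    binary: LogisticMixedFit
    positive: PositivePartFit
    r2_binary: tuple[float, float]       # (marginal, conditional)
    r2_positive: tuple[float, float]


def fit_hurdle(records: pd.DataFrame, **design_kw) -> HurdleFit:
    """Fit both hurdle parts and their pseudo-R² values."""
    binary = fit_binary_part(records, **design_kw)
    positive = fit_positive_part(records, **design_kw)
    return HurdleFit(binary=binary, positive=positive,
                     r2_binary=pseudo_r2(binary), r2_positive=pseudo_r2(positive))


def format_hurdle_report(fit: HurdleFit) -> str:
    """Plain-text coefficient tables for both hurdle parts."""
    lines = []

    def table(title, names, est, se, stat, pv, stat_name):
        lines.append(title)
        lines.append(f"{'term':<16}{'estimate':>12}{'SE':>10}"
                     f"{stat_name:>10}{'p':>10}")
        for k in range(len(names)):
            lines.append(f"{names[k]:<16}{est[k]:>12.3f}{se[k]:>10.3f}"
                         f"{stat[k]:>10.3f}{pv[k]:>10.3g}")

    b = fit.binary
    table("Binary part: P(movement) ~ diel + lunar + month + (1|individual)",
          b.names, b.params, b.se, b.zvalues, b.pvalues, "z")
    lines.append(f"sigma_alpha = {b.sigma:.3f}")
    lines.append(f"Marginal R2: {fit.r2_binary[0]:.3f}  "
                 f"Conditional R2: {fit.r2_binary[1]:.3f}")
    lines.append("")
    p = fit.positive
    table("Positive part: rate (m/h) ~ diel + lunar + month + (1|individual)",
          p.names, p.params, p.se, p.tvalues, p.pvalues, "t")
    lines.append(f"sigma_alpha = {p.sigma_alpha:.3f}  sigma_e = {p.sigma_e:.3f}")
    lines.append(f"Marginal R2: {fit.r2_positive[0]:.3f}  "
                 f"Conditional R2: {fit.r2_positive[1]:.3f}")
    return "\n".join(lines)
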