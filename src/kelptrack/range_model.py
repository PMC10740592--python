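"""Distance-dependent detection probability and the 50%-detection range.

Range testing tows a transmitting tag away from a moored receiver while a
mobile unit records every transmission; pairing the mobile record with the
moored receiver's log yields a binary detected/missed outcome per ping at
a known distance.  The model is a logistic mixed regression of detection
on distance with a per-receiver random *slope*,

    logit p_ij = beta0 + (beta1 + b_j) * d_ij,    b_j ~ N(0, sigma_b^2),

so receivers share one intercept (a tag at zero range is heard equally
well anywhere) but differ in how fast detectability decays, e.g. inside
versus outside kelp.  The detection range is the distance of 50% detection
probability,

    d50 = -beta0 / (beta1 + b_j)        (global: b_j = 0),

used downstream as a single constant array-wide range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import great_circle_m
from .glmm import LogisticMixedFit, fit_logistic_mixed
from .io import ReceiverStation

__all__ = ["RangeFit", "build_range_observations", "fit_detection_glmm", "d50"]


@dataclass
class RangeFit:
    """Fitted detection-range model."""

    beta0: float
    beta1: float
    slope_sd: float                  # sigma_b
    b: dict                          # receiver -> predicted slope deviation
    cov: np.ndarray                  # covariance of (beta0, beta1)
    loglik: float
    converged: bool
    n_obs: int
    n_receivers: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def build_range_observations(rangetest: pd.DataFrame,
                             station: ReceiverStation) -> pd.DataFrame:
    """Turn a mobile range-test log into per-ping (distance, detected) rows.

    ``rangetest`` needs columns ``lat``, ``lon``, ``detected`` (and
    optionally ``timestamp``); distances are great-circle metres from the
    station mooring.  Returns a DataFrame with columns ``receiver_id``,
    ``distance``, ``detected``.
    """
    dist = great_circle_m(rangetest["lon"].to_numpy(), rangetest["lat"].to_numpy(),
                          station.lon, station.lat)
    return pd.DataFrame({
        "receiver_id": station.receiver_id,
        "distance": dist,
        "detected": rangetest["detected"].astype(int).to_numpy(),
    })


def fit_detection_glmm(obs: pd.DataFrame) -> RangeFit:
    """Fit the random-slope logistic detection model by Laplace ML.

    ``obs`` needs columns ``receiver_id``, ``distance``, ``detected``.
    With fewer than two receivers (or no between-receiver variance in the
    data) the fit falls back to pooled logistic regression with
    ``slope_sd = 0``.
    """
    if obs.empty:
        raise ValueError("no range observations")
    X = np.column_stack([np.ones(len(obs)), obs["distance"].to_numpy(float)])
    fit: LogisticMixedFit = fit_logistic_mixed(
        X, obs["detected"].to_numpy(float), obs["receiver_id"].to_numpy(),
        z=obs["distance"].to_numpy(float), names=["(Intercept)", "distance"])
    return RangeFit(
        beta0=float(fit.params[0]), beta1=float(fit.params[1]),
        slope_sd=fit.sigma, b=fit.ranef, cov=fit.cov, loglik=fit.loglik,
        converged=fit.converged, n_obs=fit.n_obs, n_receivers=fit.n_groups)


def d50(fit: RangeFit, receiver_id: str | None = None) -> float:
    """Distance (m) at which modeled detection probability is 50%.

    With a receiver id, uses that receiver's effective slope
    ``beta1 + b_j``; otherwise the global slope.  Raises if the effective
    slope is non-negative (no finite 50% range).
    """
    slope = fit.beta1
    if receiver_id is not None:
        if receiver_id not in fit.b:
            raise KeyError(f"no random effect for receiver {receiver_id!r}")
        slope = fit.beta1 + fit.b[receiver_id]
    if slope >= 0:
        raise ValueError("effective distance slope is non-negative; "
                         "50% detection range undefined")
    return -fit.beta0 / slope


def d50_standard_error(fit: RangeFit) -> float:
    """Delta-method SE of the global d50 = -beta0/beta1."""
    g = np.array([-1.0 / fit.beta1, fit.beta0 / fit.beta1 ** 2])
    return float(np.sqrt(g @ fit.cov @ g))
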