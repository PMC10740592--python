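"""Logistic mixed-effects model with one scalar Gaussian random effect per group.

The model is

    logit P(y_i = 1) = x_i' beta + z_i * b_{g(i)},    b_g ~ N(0, sigma^2)

where ``z`` is a known loading: ``z = 1`` gives a random intercept (one
deviation per individual), ``z = distance`` gives a random slope (one
per-receiver deviation of the distance effect).  Both uses in this package
— the detection-range model and the binary hurdle part — are instances of
this form.

Estimation maximises the Laplace-approximated marginal likelihood.  For a
candidate sigma, the joint penalised log-likelihood in (beta, b) is
concave and is maximised by Newton's method with step-halving; because the
random effect is scalar per group, the Laplace correction factorises over
groups:

    l(sigma) = sum_i log p(y_i | beta_hat, b_hat)
             - sum_g b_hat_g^2 / (2 sigma^2)
             - 1/2 sum_g log(1 + sigma^2 * S_g),
    S_g = sum_{i in g} w_i z_i^2,   w_i = mu_i (1 - mu_i).

The outer problem is a one-dimensional search over log(sigma), warm-started
between evaluations.  As sigma -> 0 the objective tends to the pooled
logistic log-likelihood, so the pooled fit is the exact boundary case.
Fixed effects are evaluated at the joint mode (the profile-Laplace shortcut
also used for fast GLMM deviance evaluation); with the group sizes used
here the difference from re-optimising beta inside the integral is far
below one standard error.

Standard errors condition on the estimated sigma: the covariance of beta
is the fixed-effect block of the inverse joint Hessian, matching common
mixed-model practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded (perfectly separable data)."""


@dataclass
class LogisticMixedFit:
    """Result of a Laplace logistic mixed fit (or its pooled boundary case)."""

    params: np.ndarray                # fixed effects beta
    names: list[str]
    cov: np.ndarray                   # covariance of beta (sigma held fixed)
    sigma: float                      # random-effect SD
    ranef: dict                       # group label -> predicted deviation b_g
    loglik: float                     # Laplace marginal log-likelihood
    converged: bool
    n_obs: int
    n_groups: int
    linpred_fixed: np.ndarray = field(repr=False)   # X beta
    linpred_full: np.ndarray = field(repr=False)    # X beta + z b

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))


def _joint_mode(X, y, z, gidx, q, sigma2, theta0, max_iter=100, tol=1e-10):
    """Newton maximisation of the penalised log-likelihood over (beta, b).

    Returns (theta, S_g at mode, cond_ll, H, converged); sigma2 may be None
    for the pooled model (no random effects, q columns absent).
    """
    n, p = X.shape
    mixed = sigma2 is not None
    dim = p + (q if mixed else 0)
    theta = theta0.copy() if theta0 is not None else np.zeros(dim)

    def unpack(th):
        return th[:p], (th[p:] if mixed else np.zeros(q))

    def penalised_ll(th):
        beta, b = unpack(th)
        eta = X @ beta + z * b[gidx] if mixed else X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if mixed:
            ll -= float(b @ b) / (2.0 * sigma2)
        return ll, eta

    ll, eta = penalised_ll(theta)
    converged = False
    for _ in range(max_iter):
        beta, b = unpack(theta)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        resid = y - mu
        g_beta = X.T @ resid
        H = np.empty((dim, dim))
        Hbb = X.T @ (w[:, None] * X)
        H[:p, :p] = Hbb
        if mixed:
            wz = w * z
            g_b = np.bincount(gidx, weights=z * resid, minlength=q) - b / sigma2
            grad = np.concatenate([g_beta, g_b])
            C = np.vstack([np.bincount(gidx, weights=wz * X[:, k], minlength=q)
                           for k in range(p)])
            D = np.bincount(gidx, weights=wz * z, minlength=q) + 1.0 / sigma2
            H[:p, p:] = C
            H[p:, :p] = C.T
            H[p:, p:] = np.diag(D)
        else:
            grad = g_beta
        if not np.all(np.isfinite(grad)):
            break
        if np.max(np.abs(grad)) < 1e-8 * max(1.0, n):
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the penalised objective
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new, eta_new = penalised_ll(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        moved = np.max(np.abs(scale * step))
        theta, ll, eta = cand, ll_new, eta_new
        if ll_new - ll < np.inf and moved < tol * (1.0 + np.max(np.abs(theta))):
            converged = True
            break
        if np.max(np.abs(theta)) > 1e8:
            break  # likelihood unbounded: separation
    beta, b = unpack(theta)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    S = np.bincount(gidx, weights=w * z * z, minlength=q)
    cond_ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    # final Hessian at the mode, for covariance extraction
    H = np.empty((dim, dim))
    H[:p, :p] = X.T @ (w[:, None] * X)
    if mixed:
        wz = w * z
        C = np.vstack([np.bincount(gidx, weights=wz * X[:, k], minlength=q)
                       for k in range(p)])
        D = np.bincount(gidx, weights=wz * z, minlength=q) + 1.0 / sigma2
        H[:p, p:] = C
        H[p:, :p] = C.T
        H[p:, p:] = np.diag(D)
    return theta, S, cond_ll, H, converged


def fit_logistic_mixed(X, y, groups, z=None, names=None,
                       check_separation=True) -> LogisticMixedFit:
    """Fit the one-random-effect logistic mixed model by Laplace ML.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix (include the intercept column).
    y : (n,) binary outcomes.
    groups : (n,) group labels (individuals, receivers, ...).
    z : (n,) random-effect loading; ``None`` means a random intercept.
    names : optional fixed-effect names.

    Returns a :class:`LogisticMixedFit`.  If the estimated random-effect SD
    collapses to the boundary the pooled logistic fit is returned with
    ``sigma = 0`` and all predicted deviations zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    q = len(labels)
    z = np.ones(n) if z is None else np.asarray(z, dtype=float).ravel()

    # pooled start
    theta_pool, _, pool_ll, H_pool, pool_conv = _joint_mode(
        X, y, z, gidx, q, None, None)
    # a perfectly separable pooled fit drives every fitted probability to
    # its outcome and the likelihood to zero; the MLE does not exist
    saturated = pool_ll > -1e-4 * n and np.max(np.abs(X @ theta_pool)) > 15.0
    if check_separation and (saturated or
                             (not pool_conv and pool_ll > -1e-6 * n)):
        raise SeparationError(
            "complete separation: pooled logistic likelihood is unbounded; "
            "reconsider the predictors or fit on pooled data")

    zscale = max(float(np.max(np.abs(z))), 1e-12)
    lo, hi = np.log(1e-7 / zscale), np.log(50.0 / zscale)
    warm = {"theta": np.concatenate([theta_pool, np.zeros(q)])}

    def negloglik(u):
        sigma2 = float(np.exp(2.0 * u))
        theta, S, cond_ll, _, conv = _joint_mode(
            X, y, z, gidx, q, sigma2, warm["theta"])
        if conv:
            warm["theta"] = theta
        b = theta[p:]
        ll = cond_ll - float(b @ b) / (2.0 * sigma2) \
            - 0.5 * float(np.sum(np.log1p(sigma2 * S)))
        return -ll

    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    sigma = float(np.exp(res.x))
    boundary = res.x < lo + 1e-2 or sigma * zscale < 1e-5

    if boundary or q < 2:
        cov = np.linalg.inv(H_pool[:p, :p])
        eta = X @ theta_pool
        return LogisticMixedFit(
            params=theta_pool, names=list(names), cov=cov, sigma=0.0,
            ranef={lab: 0.0 for lab in labels}, loglik=pool_ll,
            converged=bool(pool_conv), n_obs=n, n_groups=q,
            linpred_fixed=eta, linpred_full=eta)

    sigma2 = sigma ** 2
    theta, S, cond_ll, H, conv = _joint_mode(X, y, z, gidx, q, sigma2,
                                             warm["theta"])
    beta, b = theta[:p], theta[p:]
    loglik = cond_ll - float(b @ b) / (2.0 * sigma2) \
        - 0.5 * float(np.sum(np.log1p(sigma2 * S)))
    try:
        cov = np.linalg.inv(H)[:p, :p]
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        conv = False
    if not conv:
        warnings.warn("logistic mixed fit did not fully converge; "
                      "returning last iterate", stacklevel=2)
    eta_fixed = X @ beta
    eta_full = eta_fixed + z * b[gidx]
    return LogisticMixedFit(
        params=beta, names=list(names), cov=cov, sigma=sigma,
        ranef=dict(zip(labels.tolist(), b.tolist())), loglik=loglik,
        converged=bool(conv and res.success), n_obs=n, n_groups=q,
        linpred_fixed=eta_fixed, linpred_full=eta_full)
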