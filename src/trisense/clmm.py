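"""Cumulative link mixed models fitted by adaptive Gauss-Hermite quadrature.

Ordinal (proportional-odds) regression with a participant random
intercept: the latent response for observation ``i`` of participant
``s`` is ``eta_i = x_i' beta + u_s`` with ``u_s ~ N(0, sigma_u^2)``, and

    P(Y_i <= k) = F(theta_k - eta_i),

with strictly increasing cutpoints ``theta_1 < ... < theta_{K-1}`` and
``F`` the logistic CDF (probit available via ``link="probit"``).
The marginal likelihood integrates the random intercept out per
participant; the integral is evaluated by adaptive Gauss-Hermite
quadrature (nodes recentred at each participant's conditional mode and
rescaled by the local curvature), and maximized by quasi-Newton with
the cutpoints parametrized as (theta_1, log increments) and the random
SD on the log scale so the constraints hold by construction.

Fixed effects use treatment coding with the asynchronous condition as
reference, so a positive coefficient means synchrony raises ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps
from scipy.special import expit, log_expit, logsumexp, log_ndtr

from .stats import TestResult

__all__ = ["ClmmSpec", "ClmmFit", "build_design", "clmm_loglik", "fit_clmm", "lrt"]

_TERMS = ("vt_sync", "vv_sync", "interaction")
_BETA_CAP = 15.0


@dataclass(frozen=True)
class ClmmSpec:
    """Model specification for one questionnaire statement."""

    response: str = "S1"
    fixed_terms: Tuple[str, ...] = ("vt_sync", "vv_sync")
    n_quadrature_nodes: int = 10
    link: str = "logit"

    def __post_init__(self) -> None:
        bad = [t for t in self.fixed_terms if t not in _TERMS]
        if bad:
            raise ValueError(f"unknown fixed terms {bad}; allowed: {_TERMS}")
        if "interaction" in self.fixed_terms and not {"vt_sync", "vv_sync"} <= set(self.fixed_terms):
            raise ValueError("interaction requires both main-effect terms")
        if self.n_quadrature_nodes < 3:
            raise ValueError("need at least 3 quadrature nodes")
        if self.link not in ("logit", "probit"):
            raise ValueError("link must be 'logit' or 'probit'")


@dataclass(frozen=True)
class ClmmFit:
    """Maximum-likelihood estimates for a fitted cumulative link mixed model."""

    spec: ClmmSpec
    cutpoints: np.ndarray
    betas: Dict[str, float]
    random_sd: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    categories: Tuple[int, ...]
    separation_flag: bool = False


def build_design(data: pd.DataFrame, spec: ClmmSpec):
    """Long-format questionnaire rows -> (y codes, X, group index, categories)."""
    sub = data[data["statement"] == spec.response]
    if len(sub) == 0:
        raise ValueError(f"no rows for statement {spec.response}")
    values = sub["value"].to_numpy(dtype=float)
    if not np.allclose(values, values.round()):
        raise ValueError(f"{spec.response} has non-integer values; CLMM needs ordinal data")
    categories = tuple(int(v) for v in np.unique(values))
    if len(categories) < 2:
        raise ValueError("response is constant: nothing to model")
    y = np.searchsorted(categories, values.astype(int))
    vt = sub["condition"].str.endswith("SVT").to_numpy(dtype=float)
    vv = sub["condition"].str.startswith("SVV").to_numpy(dtype=float)
    cols = {"vt_sync": vt, "vv_sync": vv, "interaction": vt * vv}
    X = np.column_stack([cols[t] for t in spec.fixed_terms]) if spec.fixed_terms else np.empty((len(sub), 0))
    groups, group_idx = np.unique(sub["participant"].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 participants")
    return y, X, group_idx, categories


def _log_cat_prob(a: np.ndarray, b: np.ndarray, link: str) -> np.ndarray:
    """log[F(a) - F(b)] elementwise, stable for extreme arguments (a > b)."""
    if link == "logit":
        log_fa, log_fb = log_expit(a), log_expit(b)
    else:
        log_fa, log_fb = log_ndtr(a), log_ndtr(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        # F(a) - F(b) = F(a) * (1 - exp(logF(b) - logF(a))); for the lowest
        # category F(b) = 0 and the factor is exactly 1
        diff = np.where(b == -np.inf, 1.0, -np.expm1(np.minimum(log_fb - log_fa, -1e-16)))
        out = log_fa + np.log(np.maximum(diff, 1e-300))
    return out


def _dlog_cat_prob(a: np.ndarray, b: np.ndarray, logp: np.ndarray, link: str):
    """First and second derivatives of log[F(a-u) - F(b-u)] w.r.t. u at u=0 shift.

    Arguments a, b are already theta - eta - u.  Returns (d1, d2).
    """
    if link == "logit":
        fa = np.where(np.isfinite(a), expit(a) * expit(-a), 0.0)
        fb = np.where(np.isfinite(b), expit(b) * expit(-b), 0.0)
        fpa = np.where(np.isfinite(a), fa * (1.0 - 2.0 * expit(a)), 0.0)
        fpb = np.where(np.isfinite(b), fb * (1.0 - 2.0 * expit(b)), 0.0)
    else:
        fa = np.where(np.isfinite(a), sps.norm.pdf(a), 0.0)
        fb = np.where(np.isfinite(b), sps.norm.pdf(b), 0.0)
        fpa = np.where(np.isfinite(a), -a * fa, 0.0)
        fpb = np.where(np.isfinite(b), -b * fb, 0.0)
    p = np.maximum(np.exp(logp), 1e-300)
    # clip the ratios: where P is numerically zero the exact values are
    # astronomically large and only the search direction matters
    d1 = np.clip((fb - fa) / p, -1e8, 1e8)       # d/du log P (d/du F(a-u) = -f(a-u))
    d2 = np.clip((fpa - fpb) / p - d1**2, -1e16, -0.0)  # log-concave in u
    return d1, d2


def _obs_logp(u_per_obs, eta, y, theta_pad, link):
    a = theta_pad[y + 1] - eta - u_per_obs
    b = theta_pad[y] - eta - u_per_obs
    return _log_cat_prob(a, b, link), a, b


def clmm_loglik(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    cutpoints: Sequence[float],
    betas: Sequence[float],
    random_sd: float,
    n_nodes: int = 10,
    link: str = "logit",
    method: str = "agq",
) -> float:
    """Marginal log-likelihood, integrating the random intercept per group.

    ``method="agq"`` uses adaptive Gauss-Hermite quadrature with
    ``n_nodes`` nodes; ``method="quad"`` uses brute-force adaptive
    numeric integration over u in +-8 SD (slow; serves as an oracle).
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(cutpoints) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    if random_sd < 0:
        raise ValueError("random_sd must be >= 0")
    betas = np.asarray(betas, dtype=float)
    eta = X @ betas if X.size else np.zeros(len(y))
    theta_pad = np.concatenate(([-np.inf], cutpoints, [np.inf]))
    n_groups = int(group_idx.max()) + 1
    sd = max(random_sd, 1e-8)

    if method == "quad":
        total = 0.0
        for g in range(n_groups):
            sel = group_idx == g

            def dens(u, sel=sel):
                lp, _, _ = _obs_logp(u, eta[sel], y[sel], theta_pad, link)
                return np.exp(lp.sum()) * sps.norm.pdf(u, 0.0, sd)

            val, _ = integrate.quad(dens, -8.0 * sd, 8.0 * sd, epsabs=0, epsrel=1e-10, limit=400)
            total += np.log(max(val, 1e-300))
        return float(total)

    # --- adaptive GH ---
    # conditional mode per group by Newton (the integrand is log-concave)
    u = np.zeros(n_groups)
    for _ in range(100):
        lp, a, b = _obs_logp(u[group_idx], eta, y, theta_pad, link)
        d1, d2 = _dlog_cat_prob(a, b, lp, link)
        grad = np.bincount(group_idx, weights=d1, minlength=n_groups) - u / sd**2
        hess = np.bincount(group_idx, weights=d2, minlength=n_groups) - 1.0 / sd**2
        hess = np.minimum(hess, -1e-10)
        step = grad / hess
        step = np.clip(step, -5.0 * sd, 5.0 * sd)
        u_new = u - step
        if np.max(np.abs(u_new - u)) < 1e-12:
            u = u_new
            break
        u = u_new

    lp, a, b = _obs_logp(u[group_idx], eta, y, theta_pad, link)
    _, d2 = _dlog_cat_prob(a, b, lp, link)
    curv = -(np.bincount(group_idx, weights=d2, minlength=n_groups) - 1.0 / sd**2)
    tau = 1.0 / np.sqrt(np.maximum(curv, 1e-300))

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # integral of exp(l(u)) du ~ sqrt(2)*tau * sum_j w_j exp(x_j^2) exp(l(u* + sqrt2 tau x_j))
    u_nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]   # (G, J)
    log_terms = np.empty_like(u_nodes)
    for j in range(n_nodes):
        lp_j, _, _ = _obs_logp(u_nodes[group_idx, j], eta, y, theta_pad, link)
        group_lp = np.bincount(group_idx, weights=lp_j, minlength=n_groups)
        log_phi = -0.5 * np.log(2 * np.pi * sd**2) - u_nodes[:, j] ** 2 / (2 * sd**2)
        log_terms[:, j] = group_lp + log_phi + nodes[j] ** 2 + np.log(weights[j])
    log_lg = logsumexp(log_terms, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
    return float(log_lg.sum())


def _pack_x0(y, categories, n_beta):
    """Starting values: cutpoints from marginal cumulative frequencies."""
    k = len(categories)
    freq = np.bincount(y, minlength=k) / len(y)
    cum = np.clip(np.cumsum(freq)[:-1], 0.01, 0.99)
    theta = np.log(cum / (1.0 - cum))
    theta = np.maximum.accumulate(theta + 1e-6 * np.arange(k - 1))
    inc = np.maximum(np.diff(theta), 1e-3)
    return np.concatenate(([theta[0]], np.log(inc), np.zeros(n_beta), [np.log(0.5)]))


def _unpack(x, k, n_beta):
    theta1 = x[0]
    inc = np.exp(x[1 : k - 1])
    cutpoints = theta1 + np.concatenate(([0.0], np.cumsum(inc)))
    betas = x[k - 1 : k - 1 + n_beta]
    sd = np.exp(x[-1])
    return cutpoints, betas, sd


def fit_clmm(data: pd.DataFrame, spec: ClmmSpec) -> ClmmFit:
    """Fit the cumulative link mixed model for one statement by ML."""
    y, X, group_idx, categories = build_design(data, spec)
    k = len(categories)
    n_beta = X.shape[1]
    x0 = _pack_x0(y, categories, n_beta)

    def nll(x):
        cut, bet, sd = _unpack(x, k, n_beta)
        return -clmm_loglik(
            y, X, group_idx, cut, bet, sd,
            n_nodes=spec.n_quadrature_nodes, link=spec.link,
        )

    bounds = (
        [(-25.0, 25.0)]
        + [(-10.0, 5.0)] * (k - 2)
        + [(-_BETA_CAP, _BETA_CAP)] * n_beta
        + [(-6.0, 3.0)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
    cutpoints, beta_vec, sd = _unpack(res.x, k, n_beta)
    separation = bool(np.any(np.abs(beta_vec) >= _BETA_CAP - 1e-6))
    if separation:
        warnings.warn(
            f"possible separation in {spec.response}: a coefficient hit the cap {_BETA_CAP}",
            RuntimeWarning,
        )
    converged = bool(res.success) and np.isfinite(res.fun)
    return ClmmFit(
        spec=spec,
        cutpoints=cutpoints,
        betas={t: float(b) for t, b in zip(spec.fixed_terms, beta_vec)},
        random_sd=float(sd),
        loglik=float(-res.fun),
        converged=converged,
        n_obs=len(y),
        n_groups=int(group_idx.max()) + 1,
        categories=categories,
        separation_flag=separation,
    )


def lrt(full: ClmmFit, reduced: ClmmFit) -> TestResult:
    """Likelihood-ratio test of the fixed terms dropped in ``reduced``.

    chi2 = 2 (ll_full - ll_reduced) with df = the number of dropped
    fixed-effect terms; p from the chi-square upper tail.
    """
    full_terms = set(full.spec.fixed_terms)
    red_terms = set(reduced.spec.fixed_terms)
    if not red_terms < full_terms:
        raise ValueError("reduced model terms must be a strict subset of the full model's")
    if full.n_obs != reduced.n_obs or full.n_groups != reduced.n_groups:
        raise ValueError("models were fitted to different data")
    df = len(full_terms) - len(red_terms)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return TestResult(statistic_name="chi2", statistic=float(chi2), p=p, tails=2, n_used=full.n_obs)
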