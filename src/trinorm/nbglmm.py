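"""Negative-binomial GLMM with a participant random intercept and log-offset.

For counts y_i of one gene, linear predictor

    log mu_i = x_i' beta + u_{p(i)} + offset_i,      u_p ~ N(0, sigma_u^2),

with NB variance mu + phi mu^2. The marginal likelihood integrates u out per
participant; the integral is approximated by adaptive Gauss-Hermite
quadrature centred at each group's posterior mode (Laplace approximation is
the 1-node special case; 5 nodes by default). beta, log sigma_u and log phi
are maximized jointly (L-BFGS-B with finite-difference gradients over a
numba-compiled marginal log-likelihood); standard errors come from the
inverse observed information at the optimum, and Wald z = beta/SE with
two-sided normal-tail p-values.

The offset contract is exact at the optimum: adding a constant c to every
offset decreases the intercept by c and leaves every other coefficient, SE
and p-value unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import norm

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _group_nll(eta0, y, a, b, u, inv_s2, phi, zq, wq):
    """-log of one group's marginal likelihood factor; updates the mode in place."""
    # inner Newton for the posterior mode of u
    H = -inv_s2
    for _ in range(100):
        g = -u * inv_s2
        H = -inv_s2
        for i in range(a, b):
            mu = math.exp(eta0[i] + u)
            d = 1.0 + phi * mu
            g += (y[i] - mu) / d
            H -= mu * (1.0 + phi * y[i]) / (d * d)
        step = -g / H
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        u += step
        if abs(step) < 1e-11:
            break
    sd = 1.0 / math.sqrt(-H)
    r = 1.0 / phi
    lphi = math.log(phi)
    su = 1.0 / math.sqrt(inv_s2)
    m = -1.0e308
    vals = np.empty(zq.size)
    for j in range(zq.size):
        uj = u + _SQRT2 * sd * zq[j]
        lj = -0.5 * uj * uj * inv_s2 - math.log(su) - _LOG_SQRT_2PI
        for i in range(a, b):
            eta = eta0[i] + uj
            mu = math.exp(eta)
            lj += (
                math.lgamma(y[i] + r)
                - math.lgamma(r)
                - math.lgamma(y[i] + 1.0)
                + y[i] * (lphi + eta)
                - (y[i] + r) * math.log1p(phi * mu)
            )
        vals[j] = lj + zq[j] * zq[j] + math.log(wq[j])
        if vals[j] > m:
            m = vals[j]
    s = 0.0
    for j in range(zq.size):
        s += math.exp(vals[j] - m)
    return -(m + math.log(s) + 0.5 * math.log(2.0) + math.log(sd)), u


@njit(cache=True)
def _marginal_nll(theta, X, y, offset, gstart, gend, zq, wq, u_work):
    n, k = X.shape
    beta = theta[:k]
    su = math.exp(theta[k])
    phi = math.exp(theta[k + 1])
    inv_s2 = 1.0 / (su * su)
    eta0 = np.empty(n)
    for i in range(n):
        acc = offset[i]
        for j in range(k):
            acc += X[i, j] * beta[j]
        eta0[i] = acc
    total = 0.0
    for p in range(gstart.size):
        nll_p, u_new = _group_nll(
            eta0, y, gstart[p], gend[p], u_work[p], inv_s2, phi, zq, wq
        )
        u_work[p] = u_new
        total += nll_p
    return total


@dataclass
class NBGLMMFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    wald_z: pd.Series
    p_values: pd.Series
    dispersion: float
    random_intercept_sd: float
    offset_used: np.ndarray
    converged: bool
    n_obs: int
    log_likelihood: float
    degenerate: bool = False


def _poisson_irls_start(X, y, offset, iters=12):
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = math.log(max(y.mean(), 0.5)) - offset.mean()
    for _ in range(iters):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        W = mu
        XtWX = (X * W[:, None]).T @ X
        XtWz = (X * W[:, None]).T @ z
        try:
            new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = new
    return beta


def _moment_starts(X, y, offset, beta, codes):
    mu = np.exp(np.clip(X @ beta + offset, -30, 30))
    denom = np.sum(mu**2)
    phi0 = np.sum((y - mu) ** 2 - mu) / denom if denom > 0 else 0.1
    phi0 = float(np.clip(phi0, 1e-3, 5.0))
    resid = np.log((y + 0.5) / (mu + 0.5))
    gm = np.bincount(codes, weights=resid) / np.bincount(codes)
    su0 = float(np.clip(np.std(gm), 0.05, 2.0))
    return su0, phi0


def fit_nb_glmm(
    y,
    X: pd.DataFrame | np.ndarray,
    groups,
    offset=None,
    n_quadrature: int = 5,
    design_labels=None,
    max_restarts: int = 3,
) -> NBGLMMFit:
    """Fit the NB random-intercept model for one gene; see module docstring."""
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns)
        Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    else:
        Xv = np.ascontiguousarray(np.asarray(X, dtype=float))
        labels = list(design_labels) if design_labels else [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, k = Xv.shape
    if yv.shape[0] != n:
        raise ValueError("y and X must have matching length")
    if np.any(yv < 0) or np.any(yv != np.floor(yv)):
        raise ValueError("y must contain non-negative integer counts")
    offv = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if offv.shape[0] != n:
        raise ValueError("offset must have one value per sample")
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(uniques) < 2:
        raise ValueError("need >= 2 groups for a random-intercept model")

    nan_series = pd.Series(np.nan, index=labels)
    if yv.sum() == 0:
        return NBGLMMFit(
            coefficients=nan_series.copy(),
            standard_errors=nan_series.copy(),
            wald_z=nan_series.copy(),
            p_values=nan_series.copy(),
            dispersion=np.nan,
            random_intercept_sd=np.nan,
            offset_used=offv,
            converged=False,
            n_obs=n,
            log_likelihood=np.nan,
            degenerate=True,
        )

    # sort observations by group for contiguous group slices
    order = np.argsort(codes, kind="stable")
    Xs = np.ascontiguousarray(Xv[order])
    ys = yv[order]
    offs = offv[order]
    cs = codes[order]
    P = len(uniques)
    gstart = np.searchsorted(cs, np.arange(P)).astype(np.int64)
    gend = np.append(gstart[1:], n).astype(np.int64)

    zq, wq = np.polynomial.hermite.hermgauss(int(n_quadrature))

    beta0 = _poisson_irls_start(Xs, ys, offs)
    su0, phi0 = _moment_starts(Xs, ys, offs, beta0, cs)
    starts = [
        np.concatenate([beta0, [math.log(su0)], [math.log(phi0)]]),
        np.concatenate([beta0, [math.log(0.3)], [math.log(0.1)]]),
        np.concatenate([beta0, [math.log(min(su0 * 3, 2.0))], [math.log(min(phi0 * 3, 5.0))]]),
    ][: max(1, max_restarts)]

    bounds = [(None, None)] * k + [(math.log(1e-4), math.log(10.0)),
                                   (math.log(1e-8), math.log(10.0))]
    u_work = np.zeros(P)

    def nll(theta):
        v = _marginal_nll(theta, Xs, ys, offs, gstart, gend, zq, wq, u_work)
        return v if np.isfinite(v) else 1e300

    best = None
    converged = False
    for s0 in starts:
        u_work[:] = 0.0
        res = minimize(nll, s0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            converged = True
            break
    theta = best.x

    # observed information via central finite differences at the optimum
    m = k + 2
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((m, m))
    f0 = nll(theta)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = h[i]
        fpp = nll(theta + 2 * ei)
        fmm = nll(theta - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h[i] ** 2)
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll(theta + ei + ej)
                - nll(theta + ei - ej)
                - nll(theta - ei + ej)
                + nll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:k]
        if np.all(d > 0):
            se = np.sqrt(d)
        else:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # fall back to the fixed-effect block with nuisance parameters held fixed
        try:
            cov_b = np.linalg.inv(H[:k, :k])
            d = np.diag(cov_b)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            converged = False

    beta = theta[:k]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return NBGLMMFit(
        coefficients=pd.Series(beta, index=labels),
        standard_errors=pd.Series(se, index=labels),
        wald_z=pd.Series(z, index=labels),
        p_values=pd.Series(p, index=labels),
        dispersion=float(math.exp(theta[k + 1])),
        random_intercept_sd=float(math.exp(theta[k])),
        offset_used=offv,
        converged=bool(converged),
        n_obs=n,
        log_likelihood=float(-best.fun),
    )


def wald_table(fit: NBGLMMFit, coefficient_labels) -> pd.DataFrame:
    """(estimate, SE, z, p) for the named coefficients of a converged fit."""
    labels = list(coefficient_labels)
    missing = [c for c in labels if c not in fit.coefficients.index]
    if missing:
        raise ValueError(f"unknown coefficient label(s): {missing}")
    return pd.DataFrame(
        {
            "estimate": fit.coefficients[labels],
            "se": fit.standard_errors[labels],
            "z": fit.wald_z[labels],
            "p": fit.p_values[labels],
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) for sorted p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
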