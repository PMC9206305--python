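"""Gaussian linear mixed models with a single participant random intercept.

Per-gene fits are the workhorse of the stable-gene screen, so the model is
solved directly rather than through a general-purpose mixed-model routine:
for y = X b + u_participant + e with u ~ N(0, s2_b) and e ~ N(0, s2_e), the
REML criterion is profiled down to a one-dimensional function of the variance
ratio lam = s2_b / s2_e. Given lam, GLS estimates and the residual variance
are closed-form via the Woodbury identity on the block-diagonal covariance,
so a bounded scalar optimization over lam is exact and fast. Boundary fits
(s2_b = 0, ICC = 0) are permitted and flagged.

The intraclass correlation coefficient (ICC) is the share of total variance
attributed to between-participant variation: s2_b / (s2_b + s2_e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import BASELINE_TIME, TIME_LEVELS, CONDITION_LEVELS


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable fixed-effects design."""


@dataclass
class LMMFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    cov_coefficients: pd.DataFrame
    t_values: pd.Series
    var_between: float
    var_residual: float
    icc: float
    converged: bool
    n_obs: int
    design_labels: tuple[str, ...]
    boundary: bool = False  # variance ratio hit zero

    def __post_init__(self):
        assert 0.0 <= self.icc <= 1.0


def _group_index(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes).astype(float)
    return codes, sizes


def _profile_pieces(lam, sizes, XtX, Xty, yty, Sx, Sy):
    # a' W b = a'b - sum_p c_p (sum a)_p (sum b)_p with W = (I + lam ZZ')^-1
    c = lam / (1.0 + lam * sizes)
    XtWX = XtX - (Sx.T * c) @ Sx
    XtWy = Xty - Sx.T @ (c * Sy)
    yWy = yty - np.sum(c * Sy * Sy)
    return XtWX, XtWy, yWy


def _neg2_reml(lam, n, k, sizes, XtX, Xty, yty, Sx, Sy):
    XtWX, XtWy, yWy = _profile_pieces(lam, sizes, XtX, Xty, yty, Sx, Sy)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, XtWy)
    rss = yWy - beta @ XtWy
    if rss <= 0:
        rss = 1e-300
    sig2 = rss / (n - k)
    return (n - k) * np.log(sig2) + np.sum(np.log1p(lam * sizes)) + logdet_xwx


def fit_reml(
    y,
    X: pd.DataFrame | np.ndarray,
    groups,
    design_labels: tuple[str, ...] | None = None,
) -> LMMFit:
    """REML fit of a random-intercept model; see module docstring.

    ``X`` must be full column rank (aliased columns raise
    :class:`DesignError` naming the offenders) and at least two distinct
    groups are required.
    """
    if isinstance(X, pd.DataFrame):
        labels = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        labels = design_labels or tuple(f"x{i}" for i in range(Xv.shape[1]))
    yv = np.asarray(y, dtype=float)
    n, k = Xv.shape
    if yv.shape[0] != n or len(groups) != n:
        raise ValueError("y, X and groups must have matching length")
    if np.linalg.matrix_rank(Xv) < k:
        # name aliased columns: those whose removal restores full rank
        aliased = []
        for j in range(k):
            others = np.delete(Xv, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xv):
                aliased.append(labels[j])
        raise DesignError(f"rank-deficient design; aliased columns: {aliased}")
    codes, sizes = _group_index(groups)
    if sizes.size < 2:
        raise ValueError("need >= 2 groups for a random-intercept model")

    XtX = Xv.T @ Xv
    Xty = Xv.T @ yv
    yty = float(yv @ yv)
    P = sizes.size
    Sx = np.zeros((P, k))
    np.add.at(Sx, codes, Xv)
    Sy = np.bincount(codes, weights=yv)

    def crit_h(h):
        lam = h / (1.0 - h)
        return _neg2_reml(lam, n, k, sizes, XtX, Xty, yty, Sx, Sy)

    # coarse grid on the ICC scale, then bounded refinement around the best
    grid = np.linspace(0.0, 0.999, 81)
    vals = np.array([crit_h(h) for h in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(crit_h, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    h_hat, best = res.x, res.fun
    converged = bool(res.success) or np.isfinite(best)
    if vals[0] <= best:  # boundary: no between-participant variance
        h_hat, best = 0.0, vals[0]
    lam = h_hat / (1.0 - h_hat)

    XtWX, XtWy, yWy = _profile_pieces(lam, sizes, XtX, Xty, yty, Sx, Sy)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(yWy - beta @ XtWy, 1e-300)
    sig2 = rss / (n - k)
    cov = sig2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.nan)
    return LMMFit(
        coefficients=pd.Series(beta, index=list(labels)),
        standard_errors=pd.Series(se, index=list(labels)),
        cov_coefficients=pd.DataFrame(cov, index=list(labels), columns=list(labels)),
        t_values=pd.Series(t, index=list(labels)),
        var_between=float(lam * sig2),
        var_residual=float(sig2),
        icc=float(h_hat),
        converged=converged,
        n_obs=n,
        design_labels=labels,
        boundary=bool(h_hat == 0.0),
    )


def icc(fit: LMMFit) -> float:
    """Between-participant variance over total variance, in [0, 1]."""
    return fit.var_between / (fit.var_between + fit.var_residual)


def condition_t_max(fit: LMMFit, condition_labels) -> float:
    """Max over the named (non-intercept) coefficients of |t|."""
    condition_labels = list(condition_labels)
    if not condition_labels:
        raise ValueError("condition_labels must be non-empty")
    if "intercept" in condition_labels:
        raise ValueError("the intercept is not a study-condition coefficient")
    missing = [c for c in condition_labels if c not in fit.t_values.index]
    if missing:
        raise ValueError(f"unknown coefficient label(s): {missing}")
    return float(fit.t_values[condition_labels].abs().max())


# ---------------------------------------------------------------------------
# design construction


def screening_design(
    meta: pd.DataFrame,
    include_volume: bool = True,
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Fixed-effects design for the stability screen.

    Intercept + time dummies (vs week 0 baseline) + volume dummy (moderate vs
    low) + time x volume interactions; every non-intercept column represents a
    study condition and feeds the max-|t| screen.
    """
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    for t in TIME_LEVELS:
        if t == BASELINE_TIME:
            continue
        X[t] = (meta["time"] == t).astype(float)
    if include_volume:
        X["volume_moderate"] = (meta["condition"] == CONDITION_LEVELS[1]).astype(float)
        if include_interactions:
            for t in TIME_LEVELS:
                if t == BASELINE_TIME:
                    continue
                X[f"{t}:volume_moderate"] = X[t] * X["volume_moderate"]
    return X


def time_design(meta: pd.DataFrame, include_volume: bool = False) -> pd.DataFrame:
    """Intercept + time dummies (legs pooled as replicates by default)."""
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    for t in TIME_LEVELS:
        if t == BASELINE_TIME:
            continue
        X[t] = (meta["time"] == t).astype(float)
    if include_volume:
        X["volume_moderate"] = (meta["condition"] == CONDITION_LEVELS[1]).astype(float)
    return X


def time_cell_means_design(meta: pd.DataFrame) -> pd.DataFrame:
    """One indicator per time level (no intercept): coefficients are the
    per-time estimated means."""
    X = pd.DataFrame(index=meta.index)
    for t in TIME_LEVELS:
        X[t] = (meta["time"] == t).astype(float)
    return X


def condition_labels(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c != "intercept"]
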