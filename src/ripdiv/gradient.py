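"""Elevation-diversity gradient models.

Fits the smooth elevation response of a per-site diversity metric with
river identity and river direction as random intercepts — a Gaussian
additive mixed model estimated as one penalized least-squares problem:

* cubic B-spline basis for elevation with an exact curvature penalty
  (integral of squared second derivative), whose null space is exactly
  the straight lines;
* the wiggly spline components and both sets of random intercepts are
  Gaussian random effects; their variance ratios are chosen by REML
  (GCV fallback), so the smoothing parameter and the shrinkage of the
  river intercepts come from the same criterion.

Also provides the peak locator (argmax of the fitted curve on a 1-masl
grid, boundary maxima classified "monotone") and a polynomial Gaussian
GLM for the conservation-value-vs-elevation curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .core_data import SiteTable

logger = logging.getLogger("ripdiv")

__all__ = ["SmoothFit", "fit_elevation_smooth", "peak_location",
           "PolyFit", "fit_cvi_glm"]


# ---------------------------------------------------------------------------
# B-spline basis with exact curvature penalty
# ---------------------------------------------------------------------------

def _knots(x: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """Clamped knot vector giving exactly ``k`` B-spline basis functions."""
    if k < degree + 1:
        raise ValueError(f"k must be >= {degree + 1} for cubic splines")
    n_interior = k - degree - 1
    lo, hi = float(x.min()), float(x.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _basis(x: np.ndarray, t: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.clip(x, t[0], t[-1])
    return BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()


def _curvature_penalty(t: np.ndarray, k: int, degree: int = 3) -> np.ndarray:
    """P[i,j] = integral of B_i''(x) B_j''(x) dx, exact via Simpson.

    Second derivatives of cubic B-splines are piecewise linear, so the
    integrand is piecewise quadratic and Simpson's rule on each knot
    span is exact. The null space of P is exactly {1, x}.
    """
    spans = np.unique(t)
    P = np.zeros((k, k))
    eye = np.eye(k)
    for a, b in zip(spans[:-1], spans[1:]):
        pts = np.array([a, (a + b) / 2, b])
        # d2 basis at the three Simpson nodes: (3, k)
        d2 = np.vstack([
            BSpline(t, eye[j], degree).derivative(2)(pts) for j in range(k)
        ]).T
        w = (b - a) / 6 * np.array([1, 4, 1])
        P += d2.T @ (d2 * w[:, None])
    return P


def _reparam(B: np.ndarray, P: np.ndarray, tol: float = 1e-9):
    """Split the spline into fixed (penalty null space) and wiggly parts.

    Returns X_f (n x 2; spans constants and lines) and Z_s (whitened so
    its coefficients are i.i.d. under the smoothing prior).
    """
    vals, vecs = np.linalg.eigh(P)
    scale = vals[-1]
    null = vals < tol * scale
    X_f = B @ vecs[:, null]
    lam = vals[~null]
    Z_s = B @ vecs[:, ~null] / np.sqrt(lam)
    return X_f, Z_s, vecs, null, lam


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _neg2_reml(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
               blocks: list[np.ndarray]) -> float:
    n, p = X.shape
    Vs = np.eye(n)
    for tau, Z in zip(np.exp(theta), blocks):
        Vs += tau * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(Vs)
    except np.linalg.LinAlgError:
        return np.inf
    logdetV = 2 * np.sum(np.log(np.diag(L)))
    Vi_y = np.linalg.solve(Vs, y)
    Vi_X = np.linalg.solve(Vs, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(Vs, r))
    if quad <= 0:
        return np.inf
    return logdetV + logdetX + (n - p) * np.log(quad)


def _gcv(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
         blocks: list[np.ndarray]) -> float:
    C = np.hstack([X] + blocks)
    n = len(y)
    pen = np.concatenate([np.zeros(X.shape[1])] +
                         [np.full(Z.shape[1], 1.0 / tau)
                          for tau, Z in zip(np.exp(theta), blocks)])
    A = C.T @ C + np.diag(pen)
    try:
        beta = np.linalg.solve(A, C.T @ y)
    except np.linalg.LinAlgError:
        return np.inf
    fitted = C @ beta
    edf = float(np.trace(np.linalg.solve(A, C.T @ C)))
    rss = float(((y - fitted) ** 2).sum())
    denom = (n - edf) ** 2
    return np.inf if denom <= 0 else n * rss / denom


@dataclass
class SmoothFit:
    """A fitted elevation smooth with shrunken river/direction intercepts."""

    response: str
    k: int
    smoothing: dict[str, float]            # variance ratios tau per block
    coefficients: np.ndarray               # stacked [fixed, wiggle, river, dir]
    grid: pd.DataFrame                     # elevation, fit, lower, upper (1 masl)
    edf: float                             # smooth edf in [1, k - 1]
    sigma2: float
    random_variances: dict[str, float]     # sigma2 * tau per random block
    n_used: int
    n_dropped: int
    criterion: str = "reml"
    _predictor: object = field(default=None, repr=False)

    def predict(self, elevation: np.ndarray) -> np.ndarray:
        """Population-level fitted curve (random intercepts at zero)."""
        return self._predictor(np.asarray(elevation, dtype=float))


def fit_elevation_smooth(y: pd.Series, sites: SiteTable, k: int = 5,
                         response_name: str | None = None) -> SmoothFit:
    """Fit the penalized-spline mixed model of a response on elevation.

    Sites with undefined response are dropped with a warning. Variance
    ratios for the spline wiggles and the river_id / river_direction
    intercepts are estimated by REML; if the REML surface is degenerate
    the fit falls back to GCV.
    """
    name = response_name or (y.name if y.name is not None else "response")
    df = sites.sites.loc[y.index]
    yv = y.to_numpy(dtype=float)
    ok = np.isfinite(yv)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropping %d sites with undefined response",
                       name, n_dropped)
    yv = yv[ok]
    df = df.loc[ok]
    n = len(yv)
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} sites, got {n}")
    elev = df["elevation"].to_numpy(dtype=float)
    if np.ptp(elev) == 0:
        raise ValueError("elevation is constant; no gradient to fit")
    lo_e, hi_e = float(elev.min()), float(elev.max())

    def _scale(x: np.ndarray) -> np.ndarray:
        # unit-interval elevation keeps the curvature penalty well conditioned
        return (x - lo_e) / (hi_e - lo_e)

    t = _knots(_scale(elev), k)
    B = _basis(_scale(elev), t)
    P = _curvature_penalty(t, k)
    X_f, Z_s, vecs, null_mask, lam = _reparam(B, P)

    blocks: list[np.ndarray] = [Z_s]
    block_names = ["smooth"]
    for col in ("river_id", "river_direction"):
        codes, levels = pd.factorize(df[col])
        if len(levels) >= 2:
            Z = np.eye(len(levels))[codes]
            blocks.append(Z)
            block_names.append(col)
        else:
            logger.info("%s has a single level; random intercept skipped", col)

    theta0 = np.zeros(len(blocks))
    criterion = "reml"
    # a response lying in the penalty null space (constant / exactly linear)
    # leaves zero residuals and an undefined REML; shrink all blocks away
    cf, _, _, _ = np.linalg.lstsq(X_f, yv, rcond=None)
    rss_fixed = float(((yv - X_f @ cf) ** 2).sum())
    if rss_fixed <= 1e-10 * max(1.0, float(yv @ yv)):
        taus = np.full(len(blocks), 1e-8)
    else:
        res = minimize(_neg2_reml, theta0, args=(yv, X_f, blocks),
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if not np.isfinite(res.fun):
            logger.warning("REML failed for %s; falling back to GCV", name)
            criterion = "gcv"
            res = minimize(_gcv, theta0, args=(yv, X_f, blocks),
                           method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
        taus = np.exp(np.clip(res.x, -25, 25))

    # final penalized least-squares fit at the selected variance ratios
    C = np.hstack([X_f] + blocks)
    pen = np.concatenate([np.zeros(X_f.shape[1])] +
                         [np.full(Z.shape[1], 1.0 / tau)
                          for tau, Z in zip(taus, blocks)])
    A = C.T @ C + np.diag(pen)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ C.T @ yv
    fitted = C @ beta
    H_diag_blocks = Ainv @ (C.T @ C)
    edf_all = np.diag(H_diag_blocks)
    p_f = X_f.shape[1]
    p_s = Z_s.shape[1]
    edf_smooth = float(edf_all[:p_f].sum() + edf_all[p_f:p_f + p_s].sum()) - 1.0
    rss = float(((yv - fitted) ** 2).sum())
    total_edf = float(edf_all.sum())
    sigma2 = rss / max(n - total_edf, 1.0)
    cov = sigma2 * Ainv

    grid_x = np.arange(lo_e, hi_e + 0.5, 1.0)
    vals_null = vecs[:, null_mask]
    vals_pen = vecs[:, ~null_mask] / np.sqrt(lam)

    def _predict(xg: np.ndarray) -> np.ndarray:
        Bg = _basis(_scale(xg), t)
        Cg = np.hstack([Bg @ vals_null, Bg @ vals_pen])
        return Cg @ beta[:p_f + p_s]

    Bg = _basis(_scale(grid_x), t)
    Cg = np.hstack([Bg @ vals_null, Bg @ vals_pen])
    curve = Cg @ beta[:p_f + p_s]
    var = np.einsum("ij,jk,ik->i", Cg, cov[:p_f + p_s, :p_f + p_s], Cg)
    half = 1.96 * np.sqrt(np.maximum(var, 0))
    grid = pd.DataFrame({"elevation": grid_x, "fit": curve,
                         "lower": curve - half, "upper": curve + half})

    smoothing = dict(zip(block_names, taus))
    rand_var = {nm: sigma2 * tau for nm, tau in smoothing.items() if nm != "smooth"}
    return SmoothFit(
        response=name, k=k, smoothing=smoothing, coefficients=beta,
        grid=grid, edf=edf_smooth, sigma2=sigma2, random_variances=rand_var,
        n_used=n, n_dropped=n_dropped, criterion=criterion,
        _predictor=_predict,
    )


def peak_location(fit: SmoothFit) -> float | str:
    """Argmax of the fitted curve on its 1-masl grid.

    Interior maxima return the elevation (ties broken to the lowest
    elevation); a maximum on either boundary of the observed range is
    classified ``"monotone"``.
    """
    curve = fit.grid["fit"].to_numpy()
    i = int(np.argmax(curve))
    if i == 0 or i == len(curve) - 1:
        return "monotone"
    return float(fit.grid["elevation"].iloc[i])


# ---------------------------------------------------------------------------
# CVI-elevation polynomial GLM
# ---------------------------------------------------------------------------

@dataclass
class PolyFit:
    """Gaussian polynomial GLM of a response on elevation."""

    degree: int
    coefficients: np.ndarray       # intercept first, then elevation powers
    results: object                # statsmodels results
    grid: pd.DataFrame             # elevation, fit, lower, upper


def fit_cvi_glm(cvi: pd.Series, sites: SiteTable, degree: int = 2) -> PolyFit:
    """Fit CVI (or any response) on polynomial elevation terms.

    Gaussian GLM (= OLS) with powers of elevation up to ``degree``;
    the returned grid carries the fitted curve with a pointwise 95%
    confidence interval.
    """
    df = sites.sites.loc[cvi.index]
    yv = cvi.to_numpy(dtype=float)
    ok = np.isfinite(yv)
    yv, elev = yv[ok], df["elevation"].to_numpy(dtype=float)[ok]
    if len(yv) < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} sites")
    X = np.vander(elev, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient polynomial design")
    model = sm.OLS(yv, X)
    results = model.fit()
    grid_x = np.arange(elev.min(), elev.max() + 0.5, 1.0)
    Xg = np.vander(grid_x, degree + 1, increasing=True)
    pred = results.get_prediction(Xg)
    ci = pred.conf_int(alpha=0.05)
    grid = pd.DataFrame({"elevation": grid_x, "fit": pred.predicted_mean,
                         "lower": ci[:, 0], "upper": ci[:, 1]})
    return PolyFit(degree, results.params, results, grid)
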