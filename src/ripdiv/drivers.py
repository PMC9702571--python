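"""Environmental-driver inference by AICc multimodel averaging.

The workflow behind a drivers table: screen the environmental columns
for collinearity with stepwise VIF removal, fit every subset of the
retained predictors as a Gaussian linear mixed model with a random
intercept for river identity, rank models by AICc, and combine the
ΔAICc <= 2 set into one averaged model (full averaging with zero
substitution) with unconditional standard errors and per-predictor
relative importance (sum of renormalized Akaike weights).

The mixed model is fitted by maximum likelihood profiled over the
residual variance, with a one-dimensional search over the ratio
theta = var(river) / var(residual); a single grouping factor lets each
likelihood evaluation use exact per-group whitening, which keeps the
2^p model sweep fast.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

logger = logging.getLogger("ripdiv")

__all__ = [
    "vif_scores", "stepwise_vif_filter", "aicc", "akaike_weights",
    "ModelRecord", "fit_lmm_ml", "all_subsets_fit",
    "AveragedModel", "average_top_set", "driver_analysis",
]


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def vif_scores(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j comes from regressing predictor j on all others plus an
    intercept; exact collinearity yields ``inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors for VIF")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than predictors")
    out = {}
    M = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        yj = M[:, j]
        if np.std(yj) == 0:
            raise ValueError(f"constant predictor column {col!r}")
        others = np.column_stack([np.ones(len(yj)),
                                  np.delete(M, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def stepwise_vif_filter(X: pd.DataFrame, threshold: float = 4.0
                        ) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF predictor while any VIF >= threshold.

    Returns the retained columns and a removal log of (name, VIF at
    removal time). Stops with a warning if fewer than 2 predictors
    would remain.
    """
    kept = X.copy()
    removed: list[tuple[str, float]] = []
    while kept.shape[1] >= 2:
        vifs = vif_scores(kept)
        worst = vifs.idxmax()
        if vifs[worst] < threshold:
            break
        removed.append((worst, float(vifs[worst])))
        logger.info("VIF filter removing %r (VIF=%.3g)", worst, vifs[worst])
        kept = kept.drop(columns=[worst])
    else:
        logger.warning("VIF filter stopped with fewer than 2 predictors")
    return kept, removed


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

def aicc(loglik: float, kp: int, n: int) -> float:
    """Small-sample AIC: -2 loglik + 2 kp + 2 kp (kp + 1) / (n - kp - 1)."""
    if n <= kp + 1:
        raise ValueError(f"AICc undefined for n={n}, kp={kp} (n must exceed kp + 1)")
    return -2.0 * loglik + 2.0 * kp + 2.0 * kp * (kp + 1) / (n - kp - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    """Akaike weights from AICc values: exp(-delta/2), normalized."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Gaussian LMM with one random intercept, profiled ML
# ---------------------------------------------------------------------------

def _whiten(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
            sizes: np.ndarray, theta: float):
    """Transform (y, X) so the random-intercept model becomes OLS.

    For a group of size m, (I + theta*J)^{-1/2} = I - c/m * J with
    c = 1 - 1/sqrt(1 + theta*m); whitening subtracts c * group mean.
    """
    c = 1.0 - 1.0 / np.sqrt(1.0 + theta * sizes)
    gm_y = np.bincount(codes, weights=y) / sizes
    yw = y - c[codes] * gm_y[codes]
    Xw = np.empty_like(X)
    for j in range(X.shape[1]):
        gm = np.bincount(codes, weights=X[:, j]) / sizes
        Xw[:, j] = X[:, j] - c[codes] * gm[codes]
    return yw, Xw


def fit_lmm_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> dict:
    """ML fit of y = X b + u_group + e, u ~ N(0, theta * sigma^2) per group.

    Profiles the likelihood over sigma^2 and beta, leaving a bounded
    1-D search over log(theta). Returns coefficient estimates, their
    standard errors (conditional on the estimated theta, the usual
    convention), the ML log-likelihood and the variance components.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(groups)
    sizes = np.bincount(codes).astype(float)
    n = len(y)

    def neg2ll_profiled(log_theta: float) -> float:
        theta = np.exp(log_theta)
        yw, Xw = _whiten(y, X, codes, sizes, theta)
        coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(((yw - Xw @ coef) ** 2).sum())
        logdet = float(np.log1p(theta * sizes).sum())
        return n * np.log(rss / n) + logdet

    res = minimize_scalar(neg2ll_profiled, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    theta = float(np.exp(res.x))
    # boundary check: pure OLS (theta -> 0)
    if neg2ll_profiled(-30.0) < res.fun:
        theta = 0.0
    yw, Xw = _whiten(y, X, codes, sizes, theta)
    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    rss = float(((yw - Xw @ coef) ** 2).sum())
    sigma2 = rss / n
    logdet = float(np.log1p(theta * sizes).sum())
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return {"coef": coef, "se": se, "loglik": loglik, "sigma2": sigma2,
            "theta": theta, "tau2": theta * sigma2}


# ---------------------------------------------------------------------------
# All-subsets fitting and model averaging
# ---------------------------------------------------------------------------

@dataclass
class ModelRecord:
    """One candidate model: predictor subset with its fit and AICc rank."""

    predictors: tuple[str, ...]
    estimates: dict[str, float]        # includes "(Intercept)"
    std_errors: dict[str, float]
    loglik: float
    kp: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan


def all_subsets_fit(y: pd.Series | np.ndarray, X: pd.DataFrame,
                    sites_or_groups, max_predictors: int = 15,
                    standardize: bool = True) -> list[ModelRecord]:
    """Fit every predictor subset as a river-intercept LMM, ranked by AICc.

    ``sites_or_groups`` is either a SiteTable (its river_id is used) or
    an explicit group label array. Predictors are z-scored by default
    so estimates are comparable across subsets; kp counts fixed effects
    plus the two variance components. Non-converging subsets are
    recorded as skipped with a warning.
    """
    if X.shape[1] > max_predictors:
        raise ValueError(f"{X.shape[1]} predictors exceed the 2^p guard "
                         f"({max_predictors})")
    groups = (sites_or_groups.sites["river_id"].to_numpy()
              if hasattr(sites_or_groups, "sites")
              else np.asarray(sites_or_groups))
    yv = np.asarray(y, dtype=float)
    Xs = X.copy()
    if standardize:
        Xs = (Xs - Xs.mean()) / Xs.std(ddof=0)
    cols = list(Xs.columns)
    n = len(yv)
    records: list[ModelRecord] = []
    for r in range(len(cols) + 1):
        for subset in itertools.combinations(cols, r):
            M = np.column_stack([np.ones(n)] +
                                [Xs[c].to_numpy(dtype=float) for c in subset])
            try:
                fit = fit_lmm_ml(yv, M, groups)
            except np.linalg.LinAlgError:
                logger.warning("subset %s failed to converge; excluded", subset)
                continue
            names = ["(Intercept)", *subset]
            kp = len(names) + 2
            records.append(ModelRecord(
                predictors=subset,
                estimates=dict(zip(names, fit["coef"])),
                std_errors=dict(zip(names, fit["se"])),
                loglik=fit["loglik"], kp=kp,
                aicc=aicc(fit["loglik"], kp, n),
            ))
    a = np.array([m.aicc for m in records])
    w = akaike_weights(a)
    best = a.min()
    for m, wi in zip(records, w):
        m.delta_aicc = m.aicc - best
        m.weight = float(wi)
    records.sort(key=lambda m: m.aicc)
    return records


@dataclass
class AveragedModel:
    """Model-averaged coefficients over the ΔAICc <= delta candidate set."""

    table: pd.DataFrame     # Estimate, SE, z, p, importance per term
    n_models: int
    delta: float
    conditional: bool = False

    def __str__(self) -> str:
        with pd.option_context("display.float_format", "{:.4g}".format):
            head = (f"averaged over {self.n_models} models "
                    f"(dAICc <= {self.delta:g}, "
                    f"{'conditional' if self.conditional else 'full'} averaging)")
            return head + "\n" + self.table.to_string()


def average_top_set(records: list[ModelRecord], delta: float = 2.0,
                    conditional: bool = False) -> AveragedModel:
    """Combine the ΔAICc <= delta models into one averaged model.

    Weights are renormalized within the top set. Full averaging (the
    default) substitutes 0 for a predictor absent from a model, which
    shrinks weakly supported effects; conditional averaging averages
    only over the models containing the term. Unconditional SEs combine
    within-model variance and between-model spread; p-values use the
    normal approximation. Importance is the summed renormalized weight
    of the models containing each predictor.
    """
    if not records:
        raise ValueError("no model records to average")
    top = [m for m in records if m.delta_aicc <= delta]
    w = np.array([m.weight for m in top])
    w = w / w.sum()
    terms: list[str] = []
    for m in top:
        for t in m.estimates:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        present = np.array([term in m.estimates for m in top])
        est = np.array([m.estimates.get(term, 0.0) for m in top])
        se = np.array([m.std_errors.get(term, 0.0) for m in top])
        importance = float(w[present].sum())
        if conditional:
            wc = w[present] / w[present].sum()
            avg = float(wc @ est[present])
            use = float(np.sqrt(wc @ (se[present] ** 2 + (est[present] - avg) ** 2)))
        else:
            avg = float(w @ est)
            use = float(np.sqrt(w @ (se ** 2 + (est - avg) ** 2)))
        z = avg / use if use > 0 else np.nan
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"term": term, "Estimate": avg, "SE": use, "z": z,
                     "p": p, "importance": importance})
    table = pd.DataFrame(rows).set_index("term")
    return AveragedModel(table, len(top), delta, conditional)


def driver_analysis(y: pd.Series, env: pd.DataFrame, sites_or_groups,
                    vif_threshold: float = 4.0, delta: float = 2.0,
                    conditional: bool = False) -> dict:
    """Full driver workflow for one response: VIF filter, dredge, average.

    Returns the retained predictors, the removal log, the ranked model
    records and the averaged model.
    """
    retained, removed = stepwise_vif_filter(env, threshold=vif_threshold)
    records = all_subsets_fit(y, retained, sites_or_groups)
    averaged = average_top_set(records, delta=delta, conditional=conditional)
    return {"retained": list(retained.columns), "vif_removed": removed,
            "records": records, "averaged": averaged}
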