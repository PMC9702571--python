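"""Richness-constrained null models and standardized effect sizes.

Raw functional and phylogenetic diversity both track species richness,
so departures from chance are assessed against a null that preserves
each site's richness exactly: present species are redrawn uniformly
from the regional pool (all species in the matrix) and the site's
observed positive abundances are reassigned to them in random order.
SES = (observed - null mean) / null SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CommunityMatrix, Phylogeny
from .diversity import TraitSpace, _edge_incidence, _hull_volume, faith_pd, functional_richness

logger = logging.getLogger("ripdiv")

__all__ = ["richness_null_draw", "ses_profile", "richness_decoupling_check"]


def _null_presence(pres: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random presence matrix with each row's richness preserved.

    Each site's species set is drawn uniformly without replacement from
    the full pool (columns).
    """
    n_sites, n_sp = pres.shape
    S = pres.sum(axis=1)
    order = np.argsort(rng.random((n_sites, n_sp)), axis=1)
    out = np.zeros_like(pres)
    rows = np.repeat(np.arange(n_sites), S)
    cols = np.concatenate([order[i, :S[i]] for i in range(n_sites)]) if len(rows) \
        else np.empty(0, dtype=int)
    out[rows, cols] = True
    return out


def richness_null_draw(cm: CommunityMatrix,
                       seed: int | np.random.Generator = 0) -> CommunityMatrix:
    """One richness-constrained randomization of the abundance matrix.

    Per site: its observed richness S and its multiset of positive
    abundance values are exactly preserved; which species carry them is
    uniform over the pool.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ab = cm.abundance.to_numpy()
    pres = ab > 0
    null_pres = _null_presence(pres, rng)
    out = np.zeros_like(ab)
    for i in range(ab.shape[0]):
        vals = ab[i, pres[i]]
        if len(vals):
            out[i, null_pres[i]] = rng.permutation(vals)
    return CommunityMatrix(pd.DataFrame(out, index=cm.abundance.index.copy(),
                                        columns=list(cm.abundance.columns)))


@dataclass
class NullSummary:
    """Per-site null distribution summary for one metric."""

    table: pd.DataFrame  # observed, null_mean, null_sd
    metric: str
    n_reps: int
    seed: int | None


def ses_profile(cm: CommunityMatrix, phy: Phylogeny, space: TraitSpace,
                n_reps: int = 1000, seed: int | np.random.Generator = 0,
                m_fric: int | None = 2, include_root: bool = True
                ) -> tuple[pd.DataFrame, dict[str, NullSummary]]:
    """SES of FRic and PD against the richness-constrained null.

    Returns the per-site SES table (columns ``sesFD``, ``sesPD``) plus
    the per-metric null summaries. Sites where the raw metric is
    undefined, or where the null SD is zero, get NaN (warned). FRic is
    presence-based, so only null species sets matter; null PD uses the
    same edge-incidence machinery as the observed values.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None

    pres = cm.abundance.to_numpy() > 0
    n_sites = pres.shape[0]
    S = pres.sum(axis=1)
    if m_fric is None:
        m_eff = min(space.m, int(S.min()) - 1)
        if m_eff < 1:
            raise ValueError("effective axis count < 1; pass m_fric explicitly")
    else:
        m_eff = min(m_fric, space.m)
    obs_fric = functional_richness(cm, space, m=m_eff)
    obs_pd = faith_pd(cm, phy, include_root=include_root)
    lengths, A = _edge_incidence(phy, cm.species_ids)
    Ai = A.astype(np.int32)
    coords = space.coordinates.loc[cm.species_ids].to_numpy()[:, :m_eff]
    pool_vol = (_hull_volume(coords) if m_eff >= 2
                else float(np.ptp(coords[:, 0])))

    null_pd = np.empty((n_reps, n_sites))
    null_fric = np.full((n_reps, n_sites), np.nan)
    for r in range(n_reps):
        np_pres = _null_presence(pres, rng)
        counts = Ai @ np_pres.T
        if include_root:
            used = counts > 0
        else:
            used = (counts > 0) & (counts < S[None, :])
        null_pd[r] = lengths @ used
        for i in range(n_sites):
            if S[i] >= m_eff + 1:
                if m_eff == 1:
                    null_fric[r, i] = np.ptp(coords[np_pres[i], 0])
                else:
                    vol = _hull_volume(coords[np_pres[i]])
                    if vol is not None:
                        null_fric[r, i] = vol / pool_vol

    def _ses(obs: np.ndarray, null: np.ndarray, name: str):
        import warnings as _warnings
        with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN site columns
            mean = np.nanmean(null, axis=0)
            sd = np.nanstd(null, axis=0, ddof=1)
        ses = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
        n_undef = int(np.isnan(ses).sum())
        if n_undef:
            logger.warning("%s undefined at %d sites (raw metric undefined "
                           "or null SD = 0)", name, n_undef)
        tab = pd.DataFrame({"observed": obs, "null_mean": mean, "null_sd": sd},
                           index=cm.abundance.index)
        return ses, tab

    ses_fd, tab_fd = _ses(obs_fric["FRic"].to_numpy(), null_fric, "sesFD")
    ses_pd_, tab_pd = _ses(obs_pd.to_numpy(), null_pd, "sesPD")
    prof = pd.DataFrame({"sesFD": ses_fd, "sesPD": ses_pd_},
                        index=cm.abundance.index)
    prof.index.name = "site_id"
    summaries = {
        "FRic": NullSummary(tab_fd, "FRic", n_reps, seed_val),
        "PD": NullSummary(tab_pd, "PD", n_reps, seed_val),
    }
    return prof, summaries


def richness_decoupling_check(profile: pd.DataFrame,
                              flag_threshold: float = 0.10) -> pd.DataFrame:
    """Pearson correlation of diversity columns with richness S.

    Reports r and p for every raw and standardized metric present in
    the profile, and whether |r| falls below ``flag_threshold`` — the
    conventional check that the SES step decoupled FD/PD from richness.
    Reporting only; the flag is evaluated, not enforced.
    """
    if "S" not in profile.columns:
        raise ValueError("profile must contain a richness column 'S'")
    rows = []
    s = profile["S"].to_numpy(dtype=float)
    for col in [c for c in ("shannon", "FRic", "PD", "sesFD", "sesPD")
                if c in profile.columns]:
        y = profile[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(s)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 defined sites for {col}")
        if np.std(y[ok]) == 0 or np.std(s[ok]) == 0:
            rows.append({"metric": col, "r": np.nan, "p": np.nan,
                         "n": int(ok.sum()), "decoupled": pd.NA})
            continue
        r, p = stats.pearsonr(s[ok], y[ok])
        rows.append({"metric": col, "r": r, "p": p, "n": int(ok.sum()),
                     "decoupled": bool(abs(r) < flag_threshold)})
    return pd.DataFrame(rows).set_index("metric")
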