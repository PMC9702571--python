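"""Per-site taxonomic, functional and phylogenetic diversity.

Implements the raw diversity metrics later standardized by null models:
species richness S, Shannon index H' (base 2 by default), functional
richness FRic as the convex-hull volume of a community in a
Gower/principal-coordinates trait space standardized by the pool hull,
and Faith's phylogenetic diversity PD as the branch-length sum of the
minimal subtree spanning a community (root included by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import rankdata

from .core_data import CommunityMatrix, Phylogeny, TraitTable

logger = logging.getLogger("ripdiv")

__all__ = [
    "species_richness", "shannon_index", "gower_dissimilarity",
    "TraitSpace", "build_trait_space", "functional_richness",
    "faith_pd", "diversity_profile",
]


# ---------------------------------------------------------------------------
# Taxonomic diversity
# ---------------------------------------------------------------------------

def species_richness(cm: CommunityMatrix) -> pd.Series:
    """Number of species with abundance > 0 at each site."""
    s = (cm.abundance > 0).sum(axis=1)
    return s.rename("S")


def shannon_index(cm: CommunityMatrix, log_base: float = 2.0) -> pd.Series:
    """Shannon index H' = -sum(p_i * log(p_i)) per site.

    ``log_base`` defaults to 2 (bits). Sites with zero total abundance
    get H' = 0 with a warning rather than NaN.
    """
    ab = cm.abundance.to_numpy(dtype=float)
    totals = ab.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("%d empty sites get H' = 0", int(empty.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ab / np.where(totals[:, None] == 0, 1.0, totals[:, None])
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(log_base)
    h[empty] = 0.0
    # guard tiny negative round-off on single-species sites
    h = np.maximum(h, 0.0)
    return pd.Series(h, index=cm.abundance.index, name="shannon")


# ---------------------------------------------------------------------------
# Functional diversity: Gower -> PCoA -> convex hull
# ---------------------------------------------------------------------------

def gower_dissimilarity(traits: TraitTable) -> pd.DataFrame:
    """Gower dissimilarity over mixed trait types, in [0, 1].

    Continuous traits contribute |x_i - x_j| / range, ordinal traits the
    same on ranks, categorical traits a 0/1 mismatch; contributions are
    averaged over the traits non-missing in both species of a pair. A
    zero-range trait contributes 0 (warned).
    """
    df = traits.traits
    n = len(df)
    if n < 2:
        raise ValueError("need at least 2 species for dissimilarities")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col, typ in traits.types.items():
        x = df[col]
        if typ == "categorical":
            vals = x.to_numpy(dtype=object)
            ok = pd.notna(x).to_numpy()
            contrib = (vals[:, None] != vals[None, :]).astype(float)
        else:
            v = x.to_numpy(dtype=float)
            ok = np.isfinite(v)
            if typ == "ordinal":
                v = v.copy()
                v[ok] = rankdata(v[ok])
            rng_ = np.nanmax(v[ok]) - np.nanmin(v[ok]) if ok.any() else 0.0
            if rng_ == 0:
                logger.warning("trait %r has zero range; contributes 0", col)
                contrib = np.zeros((n, n))
            else:
                contrib = np.abs(v[:, None] - v[None, :]) / rng_
        pair_ok = ok[:, None] & ok[None, :]
        num += np.where(pair_ok, np.nan_to_num(contrib), 0.0)
        den += pair_ok
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(f"species pair ({df.index[i]!r}, {df.index[j]!r}) "
                         "shares no non-missing trait")
    D = num / den
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # exact symmetry against round-off
    return pd.DataFrame(D, index=df.index, columns=df.index)


@dataclass
class TraitSpace:
    """Principal-coordinates embedding of a trait dissimilarity matrix."""

    coordinates: pd.DataFrame   # species x retained axes
    eigenvalues: np.ndarray     # all eigenvalues, descending
    correction: str             # "none" or "lingoes"
    m: int                      # retained axis count


def build_trait_space(D: pd.DataFrame, m_max: int | None = None,
                      neg_tol: float = 1e-8) -> TraitSpace:
    """Embed a dissimilarity matrix by principal coordinates analysis.

    When negative eigenvalues exceed ``neg_tol`` relative to the largest
    (the Gower matrix is not Euclidean), a Lingoes additive correction
    (d'^2 = d^2 + 2c for i != j, c = -lambda_min) is applied before
    re-embedding and recorded on the result.
    """
    Dm = np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if Dm.shape[0] != Dm.shape[1] or not np.allclose(Dm, Dm.T):
        raise ValueError("dissimilarity matrix must be square symmetric")
    if np.allclose(Dm, 0):
        raise ValueError("degenerate dissimilarity matrix (all zeros)")

    def _embed(D2: np.ndarray):
        H = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * H @ D2 @ H
        vals, vecs = eigh(G)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = _embed(Dm ** 2)
    correction = "none"
    if vals[-1] < -neg_tol * max(vals[0], 1e-300):
        c = -vals[-1]
        D2c = Dm ** 2 + 2 * c
        np.fill_diagonal(D2c, 0.0)
        vals, vecs = _embed(D2c)
        correction = "lingoes"
        logger.info("non-Euclidean dissimilarities: Lingoes correction c=%.3g", c)
    pos = vals > neg_tol * max(vals[0], 1e-300)
    n_pos = int(pos.sum())
    m = n_pos if m_max is None else min(m_max, n_pos)
    if m < 1:
        raise ValueError("no positive principal-coordinate axes")
    coords = vecs[:, :m] * np.sqrt(vals[:m])
    cdf = pd.DataFrame(coords, index=D.index,
                       columns=[f"PCo{k+1}" for k in range(m)])
    return TraitSpace(cdf, vals, correction, m)


def _hull_volume(points: np.ndarray) -> float | None:
    """Convex-hull volume (area in 2-D); None for degenerate point sets."""
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return None


def functional_richness(cm: CommunityMatrix, space: TraitSpace,
                        m: int | None = None) -> pd.DataFrame:
    """FRic per site: community hull volume over the pool hull volume.

    Axis count ``m_eff`` defaults to ``min(space.m, min site richness - 1)``
    so every site can in principle form a hull; pass ``m`` explicitly to
    fix the dimensionality instead, in which case sites with fewer than
    ``m_eff + 1`` species (or degenerate coordinates) get NaN and are
    logged. Returns columns ``FRic`` (pool-standardized, in [0, 1]) and
    ``FRic_raw`` (hull volume in trait-space units).
    """
    richness = species_richness(cm)
    if m is None:
        m_eff = min(space.m, int(richness.min()) - 1)
        if m_eff < 1:
            raise ValueError(
                "effective axis count < 1 (a site has richness <= 1); "
                "pass m explicitly to compute FRic on the richer sites")
    else:
        if m < 1:
            raise ValueError("m must be >= 1")
        m_eff = min(m, space.m)
    pool = space.coordinates.to_numpy()[:, :m_eff]
    pool_vol = _hull_volume(pool) if m_eff >= 2 else float(np.ptp(pool[:, 0]))
    if not pool_vol:
        raise ValueError("species pool is degenerate in the retained axes")
    sp_index = {s: k for k, s in enumerate(space.coordinates.index)}
    missing = [s for s in cm.species_ids if s not in sp_index]
    if missing:
        raise ValueError(f"species missing from trait space: {missing}")
    cols = np.array([sp_index[s] for s in cm.species_ids])
    pres = cm.abundance.to_numpy() > 0
    raw = np.full(len(cm.site_ids), np.nan)
    n_undef = 0
    for i in range(pres.shape[0]):
        idx = cols[pres[i]]
        if len(idx) < m_eff + 1:
            n_undef += 1
            continue
        pts = space.coordinates.to_numpy()[idx][:, :m_eff]
        if m_eff == 1:
            raw[i] = float(np.ptp(pts[:, 0]))
        else:
            vol = _hull_volume(pts)
            if vol is None:
                n_undef += 1
                continue
            raw[i] = vol
    if n_undef:
        logger.info("FRic undefined at %d sites (too few species or "
                    "degenerate coordinates) with m_eff=%d", n_undef, m_eff)
    out = pd.DataFrame({"FRic": raw / pool_vol, "FRic_raw": raw},
                       index=cm.abundance.index)
    return out


# ---------------------------------------------------------------------------
# Phylogenetic diversity
# ---------------------------------------------------------------------------

def _edge_incidence(phy: Phylogeny, species_order: list[str]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Edge lengths and (edges x species) incidence of the rooted tree.

    Row e, column s is True when edge e lies on the path from the root
    to tip s; Faith's PD of any species set is then a masked sum of the
    length vector.
    """
    tree = phy.tree
    idx = {label: k for k, label in enumerate(species_order)}
    missing = [t for t in species_order if t not in set(phy.tip_labels)]
    if missing:
        raise ValueError(f"species not on the tree: {missing}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    nsp = len(species_order)
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        mask = np.zeros(nsp, dtype=bool)
        if node.is_leaf():
            if node.taxon.label in idx:
                mask[idx[node.taxon.label]] = True
        else:
            for c in node.child_nodes():
                mask |= below[id(c)]
        below[id(node)] = mask
        if node.parent_node is not None and node.edge.length is not None:
            lengths.append(float(node.edge.length))
            rows.append(mask)
    return np.asarray(lengths), np.vstack(rows)


def faith_pd(cm: CommunityMatrix, phy: Phylogeny,
             include_root: bool = True) -> pd.Series:
    """Faith's PD: branch lengths of the minimal subtree spanning each site.

    With ``include_root`` (default) the subtree is rooted at the tree
    root, so a single-species site already accrues its full root-to-tip
    path; without it, edges above the species' MRCA are excluded.
    Empty sites get PD = 0 with a warning.
    """
    lengths, A = _edge_incidence(phy, cm.species_ids)
    pres = (cm.abundance.to_numpy() > 0)
    counts = A.astype(int) @ pres.T          # edges x sites
    S = pres.sum(axis=1)                     # per-site richness
    if include_root:
        used = counts > 0
    else:
        used = (counts > 0) & (counts < S[None, :])
    pd_vals = lengths @ used
    empty = S == 0
    if empty.any():
        logger.warning("%d empty sites get PD = 0", int(empty.sum()))
    pd_vals = np.where(empty, 0.0, pd_vals)
    return pd.Series(pd_vals, index=cm.abundance.index, name="PD")


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

def diversity_profile(cm: CommunityMatrix, traits: TraitTable, phy: Phylogeny,
                      m_fric: int | None = 2, log_base: float = 2.0,
                      include_root: bool = True) -> pd.DataFrame:
    """Per-site table of S, H', FRic (+raw) and PD, in stable column order."""
    space = build_trait_space(gower_dissimilarity(traits))
    fric = functional_richness(cm, space, m=m_fric)
    prof = pd.DataFrame({
        "S": species_richness(cm),
        "shannon": shannon_index(cm, log_base=log_base),
        "FRic": fric["FRic"],
        "FRic_raw": fric["FRic_raw"],
        "PD": faith_pd(cm, phy, include_root=include_root),
    })
    prof.index.name = "site_id"
    return prof
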