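"""Blomberg's K phylogenetic signal with a permutation test.

K compares the observed ratio of cross-species trait variance to
phylogenetically corrected variance against its expectation under
Brownian motion on the given tree; K = 1 under BM, K < 1 when close
relatives are less similar than BM predicts, K > 1 when more.

The significance test permutes trait values across tips and asks how
often the permuted phylogenetic mean squared error is at most the
observed one (small observed MSE = values fit the tree well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata

from .core_data import Phylogeny, TraitTable

logger = logging.getLogger("ripdiv")

__all__ = ["PhyloCovariance", "phylo_vcv", "blomberg_k",
           "signal_permutation_test", "SignalResult", "signal_table",
           "encode_trait"]


@dataclass
class PhyloCovariance:
    """Species x species shared root-to-MRCA path lengths V, with tip order."""

    V: np.ndarray
    tip_order: list[str]

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("V must be square")
        if not np.allclose(V, V.T):
            raise ValueError("V must be symmetric")
        self.V = V

    def reorder(self, order: list[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in order]
        return PhyloCovariance(self.V[np.ix_(idx, idx)], list(order))


def phylo_vcv(phy: Phylogeny) -> PhyloCovariance:
    """Phylogenetic covariance: V[i, j] = depth of the MRCA of tips i, j.

    Diagonal entries are root-to-tip distances. Requires a rooted tree
    with branch lengths.
    """
    tree = phy.tree
    if tree.seed_node is None:
        raise ValueError("tree must be rooted")
    tips = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in tips]
    tip_index = {id(lf): i for i, lf in enumerate(tips)}
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    n = len(tips)
    V = np.zeros((n, n))
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = tip_index[id(node)]
            tipsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
        else:
            kids = [tipsets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ia = np.asarray(kids[a])
                    ib = np.asarray(kids[b])
                    V[np.ix_(ia, ib)] = d
                    V[np.ix_(ib, ia)] = d
            tipsets[id(node)] = [i for k in kids for i in k]
    return PhyloCovariance(V, labels)


def _chol(V: np.ndarray):
    """Cholesky of V, with a tiny ridge only if numerically singular."""
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * np.trace(V) / V.shape[0]
        logger.warning("V numerically singular; adding ridge %.3g", ridge)
        return cho_factor(V + ridge * np.eye(V.shape[0]), lower=True)


def _k_pieces(V: np.ndarray):
    """Quantities of the K statistic that depend only on the tree."""
    n = V.shape[0]
    c = _chol(V)
    Wi1 = cho_solve(c, np.ones(n))
    s1 = float(np.ones(n) @ Wi1)            # 1' V^-1 1
    expected = (np.trace(V) - n / s1) / (n - 1)
    return c, Wi1, s1, expected


def blomberg_k(trait_values: np.ndarray | pd.Series,
               vcv: PhyloCovariance) -> float:
    """Blomberg's K of a continuous trait on the tree behind ``vcv``.

    K = (MSE0/MSE)_observed / (MSE0/MSE)_BM, with the phylogenetically
    weighted ancestral mean a = (1'V^-1 x)/(1'V^-1 1), MSE0 the ordinary
    variance about a, MSE the V^-1-weighted one, and the BM expectation
    (tr(V) - n/(1'V^-1 1)) / (n - 1).
    """
    x = np.asarray(trait_values, dtype=float)
    V = vcv.V
    n = len(x)
    if n != V.shape[0]:
        raise ValueError("trait length does not match V")
    if n < 3:
        raise ValueError("need at least 3 tips")
    if np.std(x) == 0:
        raise ValueError("trait has zero variance")
    c, Wi1, s1, expected = _k_pieces(V)
    a = float(x @ Wi1) / s1
    d = x - a
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ cho_solve(c, d)) / (n - 1)
    return (mse0 / mse) / expected


@dataclass
class SignalResult:
    """K with its permutation p-value for one trait."""

    trait: str
    K: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def signal_permutation_test(trait_values: np.ndarray | pd.Series,
                            vcv: PhyloCovariance, n_perm: int = 1000,
                            seed: int | np.random.Generator = 0,
                            trait_name: str = "trait") -> SignalResult:
    """Tip-permutation significance test for phylogenetic signal.

    p = (1 + #{permutations with MSE <= observed MSE}) / (n_perm + 1);
    the phylogenetic MSE is smallest when trait values align with the
    tree, so small p means stronger signal than random tip shuffles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(trait_values, dtype=float)
    V = vcv.V
    n = len(x)
    k_obs = blomberg_k(x, vcv)
    c, Wi1, s1, _ = _k_pieces(V)
    W = cho_solve(c, np.eye(n))  # explicit inverse: reused by every permutation

    def mse(vals: np.ndarray) -> np.ndarray:
        # rows of vals are permutations; MSE = x'Wx - (1'Wx)^2 / (1'W1)
        xw = vals @ W
        quad = np.einsum("ij,ij->i", xw, vals)
        lin = vals @ Wi1
        return (quad - lin ** 2 / s1) / (n - 1)

    obs = float(mse(x[None, :])[0])
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)])
    null = mse(perms)
    p = (1 + int((null <= obs + 1e-12 * abs(obs)).sum())) / (n_perm + 1)
    return SignalResult(trait_name, k_obs, p, n_perm)


def encode_trait(values: pd.Series, trait_type: str) -> np.ndarray:
    """Reduce a trait column to one continuous score for the K test.

    Continuous traits pass through; ordinal traits are rank-scored;
    categorical traits are one-hot encoded and projected on the first
    principal component of the indicator matrix (sign fixed by the
    first loading). The categorical reduction is a declared convention,
    not a canonical one — K for such traits should be read as a rough
    screen.
    """
    if trait_type == "continuous":
        return values.to_numpy(dtype=float)
    if trait_type == "ordinal":
        return rankdata(values.to_numpy(dtype=float))
    if trait_type == "categorical":
        dummies = pd.get_dummies(values).to_numpy(dtype=float)
        centered = dummies - dummies.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        load = vt[0]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        return centered @ load
    raise ValueError(f"unknown trait type {trait_type!r}")


def signal_table(traits: TraitTable, phy: Phylogeny, n_perm: int = 1000,
                 seed: int = 0) -> pd.DataFrame:
    """K and permutation p per trait, tips aligned to the trait table."""
    vcv = phylo_vcv(phy).reorder(traits.species_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for col, typ in traits.types.items():
        if typ != "continuous":
            logger.info("trait %r (%s) encoded to a continuous score for K", col, typ)
        x = encode_trait(traits.traits[col], typ)
        res = signal_permutation_test(x, vcv, n_perm=n_perm, seed=rng,
                                      trait_name=col)
        rows.append({"trait": col, "K": res.K, "p": res.p, "n_perm": res.n_perm})
    return pd.DataFrame(rows).set_index("trait")
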