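"""Conservation value index (CVI).

Per site, CVI = sum over present species of log(a_i + 1) * e_i, where
a_i is the species' abundance and e_i its conservation weight: 1 for
unthreatened species, 4 for class-II and 8 for class-I nationally
protected species. The log dampens abundance so that rare protected
species dominate the score. Log base 10 by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CONSERVATION_WEIGHTS, CommunityMatrix, ConservationMap

__all__ = ["CviProfile", "cvi_profile"]


@dataclass
class CviProfile:
    """Per-site CVI values with the per-species contribution breakdown."""

    values: pd.Series        # site -> CVI
    breakdown: pd.DataFrame  # long table: site_id, species_id, abundance, weight, term
    log_base: float


def cvi_profile(cm: CommunityMatrix, status: ConservationMap,
                log_base: float = 10.0) -> CviProfile:
    """Compute the conservation value index for every site.

    Every species present anywhere in the matrix must carry a weight
    from {1, 4, 8}; empty sites score 0.
    """
    weights = status.weights
    missing = [s for s in cm.species_ids if s not in weights.index]
    if missing:
        raise ValueError(f"species without conservation weight: {missing}")
    bad = set(weights.loc[cm.species_ids].unique()) - set(CONSERVATION_WEIGHTS)
    if bad:
        raise ValueError(f"conservation weights outside {set(CONSERVATION_WEIGHTS)}: "
                         f"{sorted(bad)}")
    ab = cm.abundance.to_numpy(dtype=float)
    e = weights.loc[cm.species_ids].to_numpy(dtype=float)
    terms = np.log1p(ab) / np.log(log_base) * e[None, :]
    terms = np.where(ab > 0, terms, 0.0)
    values = pd.Series(terms.sum(axis=1), index=cm.abundance.index, name="CVI")

    site_idx, sp_idx = np.nonzero(ab > 0)
    breakdown = pd.DataFrame({
        "site_id": np.asarray(cm.site_ids)[site_idx],
        "species_id": np.asarray(cm.species_ids)[sp_idx],
        "abundance": ab[site_idx, sp_idx].astype(int),
        "weight": e[sp_idx].astype(int),
        "term": terms[site_idx, sp_idx],
    })
    return CviProfile(values, breakdown, log_base)
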