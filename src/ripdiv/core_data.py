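"""Domain types, file I/O and validation for riparian community datasets.

The analysis operates on five tables that together describe a survey of
bird communities along submontane rivers:

* a site x species abundance matrix (point-count totals),
* a species x trait table with mixed continuous/ordinal/categorical traits,
* a rooted phylogeny with branch lengths over the species pool,
* a site table with elevation, river membership and environmental columns,
* a species -> conservation-weight map (national protection classes).

All tables are carried as pandas objects inside thin dataclass wrappers
whose job is invariant checking and name-space reconciliation; the
phylogeny is a :class:`dendropy.Tree`. Identifiers (site and species
names) are the public contract; positional indices are internal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("ripdiv")

#: trait columns must carry one of these declared types
TRAIT_TYPES = ("continuous", "ordinal", "categorical")

#: environmental columns expected in a site table, in canonical order
ENV_COLUMNS = (
    "Forest", "Shrub", "Herb", "Bared",
    "Lnum", "Bar", "Width", "Sinuosity", "H_SD",
)

#: site-table percentage columns constrained to [0, 100]
PERCENT_COLUMNS = ("Forest", "Shrub", "Herb", "Bared")

#: allowed conservation weights: 1 unthreatened, 4 class-II, 8 class-I
CONSERVATION_WEIGHTS = (1, 4, 8)

#: reserved species-id used to persist trait types inside the traits CSV
_TYPE_ROW = "_type_"


def _exact_numeric(series: pd.Series) -> pd.Series:
    """String -> number conversion via strtod (bit-exact round trips).

    pandas' fast to_numeric parser can lose the last digits of a float;
    numpy's astype goes through strtod and round-trips repr exactly.
    Integer-looking columns stay integers.
    """
    if pd.api.types.is_numeric_dtype(series):
        return series
    try:
        return series.astype("int64")
    except (ValueError, TypeError):
        return series.astype(float)


class DataError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Sites x species abundance counts.

    ``abundance`` is a DataFrame indexed by site id with one integer
    column per species. Presence means abundance > 0.
    """

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.shape[0] < 1 or ab.shape[1] < 1:
            raise DataError("community matrix needs at least 1 site and 1 species")
        if ab.index.duplicated().any():
            raise DataError("duplicate site identifiers in community matrix")
        if ab.columns.duplicated().any():
            raise DataError("duplicate species identifiers in community matrix")
        vals = ab.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise DataError("community matrix must be numeric")
        if np.isnan(vals.astype(float)).any():
            raise DataError("community matrix contains missing values")
        if (vals < 0).any():
            raise DataError("community matrix contains negative abundances")
        if not np.allclose(vals, np.round(vals)):
            raise DataError("community matrix abundances must be integer counts")
        self.abundance = ab.astype(int)

    @property
    def site_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (abundance > 0)."""
        return self.abundance > 0

    def richness(self) -> pd.Series:
        return (self.abundance > 0).sum(axis=1)

    def restrict_species(self, species: Sequence[str]) -> "CommunityMatrix":
        keep = [s for s in self.species_ids if s in set(species)]
        return CommunityMatrix(self.abundance[keep])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str).str.strip()
        df.columns = df.columns.astype(str).str.strip()
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.abundance.to_csv(path, index_label="site_id")


@dataclass
class TraitTable:
    """Species x trait values with a declared type per trait column."""

    traits: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        tr = self.traits
        if tr.index.duplicated().any():
            raise DataError("duplicate species in trait table")
        missing = [c for c in tr.columns if c not in self.types]
        if missing:
            raise DataError(f"trait columns without a declared type: {missing}")
        bad = {c: t for c, t in self.types.items() if t not in TRAIT_TYPES}
        if bad:
            raise DataError(f"unknown trait types: {bad}")
        for col, typ in self.types.items():
            if typ in ("continuous", "ordinal"):
                try:
                    vals = _exact_numeric(tr[col])
                except (ValueError, TypeError) as exc:
                    raise DataError(f"non-numeric {typ} trait {col!r}: {exc}")
                if not np.isfinite(vals.to_numpy(dtype=float)).all():
                    raise DataError(f"non-finite values in {typ} trait {col!r}")
                self.traits[col] = vals

    @property
    def species_ids(self) -> list[str]:
        return list(self.traits.index)

    def restrict_species(self, species: Sequence[str]) -> "TraitTable":
        keep = [s for s in self.species_ids if s in set(species)]
        return TraitTable(self.traits.loc[keep].copy(), dict(self.types))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        raw = pd.read_csv(path, index_col=0, dtype=str)
        raw.index = raw.index.astype(str).str.strip()
        if _TYPE_ROW in raw.index:
            types = {c: str(v).strip() for c, v in raw.loc[_TYPE_ROW].items()}
            raw = raw.drop(index=_TYPE_ROW)
        else:
            # fall back to dtype inference: numeric -> continuous
            types = {}
            for c in raw.columns:
                as_num = pd.to_numeric(raw[c], errors="coerce")
                types[c] = "continuous" if as_num.notna().all() else "categorical"
            logger.warning("trait CSV has no %r row; inferred types %s", _TYPE_ROW, types)
        df = raw.copy()
        for c in df.columns:
            if types.get(c) in ("continuous", "ordinal"):
                df[c] = _exact_numeric(df[c])
        return cls(df, types)

    def to_csv(self, path: str | Path) -> None:
        out = self.traits.astype(object).copy()
        out.loc[_TYPE_ROW] = [self.types[c] for c in out.columns]
        out = out.loc[[_TYPE_ROW] + [i for i in out.index if i != _TYPE_ROW]]
        out.to_csv(path, index_label="species_id")


@dataclass
class Phylogeny:
    """Rooted tree with non-negative branch lengths; tips are species ids."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise DataError("phylogeny tip labels are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise DataError("phylogeny has an edge without a branch length")
            if edge.length < 0:
                raise DataError("phylogeny has a negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def restrict_species(self, species: Sequence[str]) -> "Phylogeny":
        keep = set(species)
        sub = self.tree.clone(depth=1)
        sub.retain_taxa_with_labels([s for s in self.tip_labels if s in keep])
        return Phylogeny(sub)

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True,
                                     rooting="default-rooted")
        except Exception as exc:
            raise DataError(f"malformed Newick string: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_newick(cls, path: str | Path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick",
                preserve_underscores=True, rooting="default-rooted",
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise DataError(f"malformed Newick file {path}: {exc}") from exc
        for lf in tree.leaf_node_iter():
            lf.taxon.label = lf.taxon.label.strip()
        return cls(tree)

    def to_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True, unquoted_underscores=True)

    def as_newick_string(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True)


@dataclass
class SiteTable:
    """Per-site elevation (masl), river membership and environment columns."""

    sites: pd.DataFrame

    REQUIRED = ("elevation", "river_id", "river_direction")

    def __post_init__(self) -> None:
        df = self.sites
        if df.index.duplicated().any():
            raise DataError("duplicate site identifiers in site table")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DataError(f"site table missing required columns: {missing}")
        if not np.isfinite(df["elevation"].to_numpy(dtype=float)).all():
            raise DataError("non-finite elevation")

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def elevation(self) -> pd.Series:
        return self.sites["elevation"]

    def environment(self, columns: Sequence[str] = ENV_COLUMNS) -> pd.DataFrame:
        present = [c for c in columns if c in self.sites.columns]
        return self.sites[present]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteTable":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str).str.strip()
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.sites.to_csv(path, index_label="site_id")


@dataclass
class ConservationMap:
    """Species -> conservation weight e_i in {1, 4, 8}."""

    weights: pd.Series

    def __post_init__(self) -> None:
        w = self.weights
        if w.index.duplicated().any():
            raise DataError("duplicate species in conservation map")
        self.weights = w.astype(int)

    @property
    def species_ids(self) -> list[str]:
        return list(self.weights.index)

    def restrict_species(self, species: Sequence[str]) -> "ConservationMap":
        keep = [s for s in self.species_ids if s in set(species)]
        return ConservationMap(self.weights.loc[keep].copy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConservationMap":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str).str.strip()
        return cls(df.iloc[:, 0])

    def to_csv(self, path: str | Path) -> None:
        self.weights.rename("weight").to_csv(path, index_label="species_id")


@dataclass
class Dataset:
    """Bundle of the five domain types over a reconciled species pool."""

    community: CommunityMatrix
    traits: TraitTable
    phylogeny: Phylogeny
    sites: SiteTable
    status: ConservationMap

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write all five tables in the canonical on-disk formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "community": out / "community.csv",
            "traits": out / "traits.csv",
            "tree": out / "tree.nwk",
            "sites": out / "sites.csv",
            "status": out / "status.csv",
        }
        self.community.to_csv(paths["community"])
        self.traits.to_csv(paths["traits"])
        self.phylogeny.to_newick(paths["tree"])
        self.sites.to_csv(paths["sites"])
        self.status.to_csv(paths["status"])
        return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-type invariant violations; empty iff the dataset is clean."""

    violations: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "dataset OK: no invariant violations"
        return "dataset violations:\n" + "\n".join(f"- {v}" for v in self.violations)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check cross-table invariants; reporting only, never raises."""
    rep = ValidationReport()
    cm, st = ds.community, ds.sites

    if (cm.abundance.to_numpy() < 0).any():
        rep.add("community: negative abundance")

    com_sp = set(cm.species_ids)
    for name, other in (
        ("traits", set(ds.traits.species_ids)),
        ("tree", set(ds.phylogeny.tip_labels)),
        ("status", set(ds.status.species_ids)),
    ):
        miss = com_sp - other
        if miss:
            rep.add(f"{name}: missing species {sorted(miss)}")

    site_ids = set(st.site_ids)
    miss_sites = set(cm.site_ids) - site_ids
    if miss_sites:
        rep.add(f"sites: missing site rows {sorted(miss_sites)}")

    for col in PERCENT_COLUMNS:
        if col in st.sites.columns:
            v = st.sites[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 100)).any():
                rep.add(f"sites: {col} outside [0, 100]")
    if "Sinuosity" in st.sites.columns:
        if (st.sites["Sinuosity"].to_numpy(dtype=float) < 1).any():
            rep.add("sites: Sinuosity < 1 (must be a channel/straight-line ratio >= 1)")

    bad_w = set(ds.status.weights.unique()) - set(CONSERVATION_WEIGHTS)
    if bad_w:
        rep.add(f"status: weights outside {set(CONSERVATION_WEIGHTS)}: {sorted(bad_w)}")

    return rep


# ---------------------------------------------------------------------------
# Loading and reconciliation
# ---------------------------------------------------------------------------

def load_dataset(
    community_path: str | Path,
    traits_path: str | Path,
    tree_path: str | Path,
    sites_path: str | Path,
    status_path: str | Path,
) -> Dataset:
    """Load the five input files and reconcile their species name spaces.

    Species sets of the community matrix, trait table, tree tips and
    status map are intersected (exact string match after whitespace
    trimming); any species discarded from a table is logged. Raises
    :class:`DataError` if the intersection is empty.
    """
    community = CommunityMatrix.from_csv(community_path)
    traits = TraitTable.from_csv(traits_path)
    phylogeny = Phylogeny.from_newick(tree_path)
    sites = SiteTable.from_csv(sites_path)
    status = ConservationMap.from_csv(status_path)

    pools = {
        "community": set(community.species_ids),
        "traits": set(traits.species_ids),
        "tree": set(phylogeny.tip_labels),
        "status": set(status.species_ids),
    }
    shared = set.intersection(*pools.values())
    if not shared:
        raise DataError("no species shared by community, traits, tree and status")
    for name, pool in pools.items():
        dropped = sorted(pool - shared)
        if dropped:
            logger.warning("dropping %d species absent elsewhere from %s: %s",
                           len(dropped), name, dropped)

    community = community.restrict_species(sorted(shared))
    order = community.species_ids  # community column order is canonical
    traits = traits.restrict_species(order)
    traits.traits = traits.traits.loc[order]
    phylogeny = phylogeny.restrict_species(order)
    status = status.restrict_species(order)
    status.weights = status.weights.loc[order]

    missing_sites = set(community.site_ids) - set(sites.site_ids)
    if missing_sites:
        raise DataError(f"community sites missing from site table: {sorted(missing_sites)}")
    sites = SiteTable(sites.sites.loc[community.site_ids].copy())

    return Dataset(community, traits, phylogeny, sites, status)


def filter_low_occurrence(cm: CommunityMatrix, min_sites: int = 3) -> CommunityMatrix:
    """Drop species detected (abundance > 0) at fewer than ``min_sites`` sites.

    Mirrors the survey-data practice of excluding rarely detected species
    before diversity analysis; the site set is unchanged.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    occ = (cm.abundance > 0).sum(axis=0)
    keep = occ[occ >= min_sites].index.tolist()
    if not keep:
        raise DataError(f"all species occur at fewer than {min_sites} sites")
    dropped = [s for s in cm.species_ids if s not in set(keep)]
    if dropped:
        logger.info("occurrence filter (min_sites=%d) removed %d species: %s",
                    min_sites, len(dropped), dropped)
    return CommunityMatrix(cm.abundance[keep])


def aggregate_quadrats(long_table: pd.DataFrame, site_col: str = "site_id") -> pd.DataFrame:
    """Reduce a quadrat-level microhabitat table to site means.

    Field protocols often measure microhabitat variables in several small
    quadrats per point-count site; the pipeline operates on site-level
    values, taken as the mean over quadrats.
    """
    return long_table.groupby(site_col).mean(numeric_only=True)
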