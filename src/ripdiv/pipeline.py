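"""One-command orchestration of the full analysis.

Loads (or synthesizes) a dataset, applies the low-occurrence species
filter, computes the diversity profile (S, H', FRic, PD), the
null-model SES columns, the conservation value index, per-trait
phylogenetic signal, elevation smooths for the four diversity
responses, the CVI-elevation polynomial fit, and the AICc-averaged
driver tables — and writes every result as CSV plus a machine-readable
run manifest. All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from importlib import metadata
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import conservation, core_data, diversity, drivers, gradient, null_models
from . import phylo_signal as signal_mod
from . import synthetic
from .core_data import Dataset

logger = logging.getLogger("ripdiv")

__all__ = ["PipelineConfig", "run_full_analysis", "apply_occurrence_filter"]

#: diversity responses smoothed against elevation
SMOOTH_RESPONSES = ("S", "shannon", "FRic", "PD")
#: responses modelled against environmental drivers
DRIVER_RESPONSES = ("S", "shannon", "sesFD", "sesPD")


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one input source must be set."""

    community_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    sites_path: str | None = None
    status_path: str | None = None
    simulation: synthetic.SimulationConfig | None = None

    n_null_reps: int = 1000
    n_perm: int = 1000
    shannon_base: float = 2.0
    cvi_base: float = 10.0
    vif_threshold: float = 4.0
    delta_aicc: float = 2.0
    spline_k: int = 5
    m_fric: int = 2
    min_occurrence_sites: int = 3
    seed: int = 0
    out_dir: str = "ripdiv_results"

    def __post_init__(self) -> None:
        paths = [self.community_path, self.traits_path, self.tree_path,
                 self.sites_path, self.status_path]
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.simulation is not None and some_paths:
            raise ValueError("set either input paths or a simulation config, not both")
        if self.simulation is None and not has_paths:
            raise ValueError("set all five input paths or a simulation config")
        for name in ("n_null_reps", "n_perm", "spline_k", "m_fric",
                     "min_occurrence_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_null_reps < 2:
            raise ValueError("n_null_reps must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = synthetic.SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def apply_occurrence_filter(ds: Dataset, min_sites: int) -> Dataset:
    """Apply the low-occurrence species filter across the whole bundle."""
    cm = core_data.filter_low_occurrence(ds.community, min_sites=min_sites)
    keep = cm.species_ids
    return Dataset(
        community=cm,
        traits=ds.traits.restrict_species(keep),
        phylogeny=ds.phylogeny.restrict_species(keep),
        sites=ds.sites,
        status=ds.status.restrict_species(keep),
    )


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _versions() -> dict[str, str]:
    out = {}
    for pkg in ("ripdiv", "numpy", "scipy", "pandas", "dendropy", "statsmodels"):
        try:
            out[pkg] = metadata.version(pkg)
        except metadata.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def run_full_analysis(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Returns a mapping of logical output names to paths. Any stage
    failure aborts with an error naming the stage; warnings from all
    stages are aggregated into the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    paths: dict[str, Path] = {}
    fmt = "%.10g"
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    stage = "setup"
    t_run = time.perf_counter()
    try:
        def _stage(name: str):
            nonlocal stage
            stage = name
            logger.info("stage %s", name)
            return time.perf_counter()

        t = _stage("load")
        if config.simulation is not None:
            sim = synthetic.SimulationConfig.from_dict(
                {**config.simulation.to_dict(), "seed": config.simulation.seed})
            ds = synthetic.generate_study(sim)
        else:
            ds = core_data.load_dataset(
                config.community_path, config.traits_path, config.tree_path,
                config.sites_path, config.status_path)
        report = core_data.validate_dataset(ds)
        if not report.ok:
            raise core_data.DataError(str(report))
        ds = apply_occurrence_filter(ds, config.min_occurrence_sites)
        logger.info("stage load done in %.2fs", time.perf_counter() - t)

        t = _stage("diversity")
        space = diversity.build_trait_space(
            diversity.gower_dissimilarity(ds.traits))
        prof = pd.DataFrame({
            "S": diversity.species_richness(ds.community),
            "shannon": diversity.shannon_index(ds.community, config.shannon_base),
        })
        fric = diversity.functional_richness(ds.community, space, m=config.m_fric)
        prof["FRic"] = fric["FRic"]
        prof["FRic_raw"] = fric["FRic_raw"]
        prof["PD"] = diversity.faith_pd(ds.community, ds.phylogeny)
        logger.info("stage diversity done in %.2fs", time.perf_counter() - t)

        t = _stage("ses")
        ses, null_sums = null_models.ses_profile(
            ds.community, ds.phylogeny, space, n_reps=config.n_null_reps,
            seed=np.random.default_rng(seeds[0]), m_fric=config.m_fric)
        prof["sesFD"] = ses["sesFD"]
        prof["sesPD"] = ses["sesPD"]
        for name, summ in null_sums.items():
            p = out / f"null_{name}.csv"
            summ.table.to_csv(p, index_label="site_id", float_format=fmt)
            paths[f"null_{name}"] = p
        decoup = null_models.richness_decoupling_check(prof)
        p = out / "decoupling.csv"
        decoup.to_csv(p, float_format=fmt)
        paths["decoupling"] = p
        logger.info("stage ses done in %.2fs", time.perf_counter() - t)

        t = _stage("cvi")
        cvi = conservation.cvi_profile(ds.community, ds.status, config.cvi_base)
        prof["CVI"] = cvi.values
        p = out / "cvi_breakdown.csv"
        cvi.breakdown.to_csv(p, index=False, float_format=fmt)
        paths["cvi_breakdown"] = p
        prof.index.name = "site_id"
        p = out / "diversity_profile.csv"
        prof.to_csv(p, float_format=fmt)
        paths["diversity_profile"] = p
        logger.info("stage cvi done in %.2fs", time.perf_counter() - t)

        t = _stage("signal")
        sig = signal_mod.signal_table(
            ds.traits, ds.phylogeny, n_perm=config.n_perm,
            seed=int(seeds[1].generate_state(1)[0] % (2 ** 31)))
        p = out / "phylo_signal.csv"
        sig.to_csv(p, float_format=fmt)
        paths["phylo_signal"] = p
        logger.info("stage signal done in %.2fs", time.perf_counter() - t)

        t = _stage("gradient")
        peaks = []
        for resp in SMOOTH_RESPONSES:
            fit = gradient.fit_elevation_smooth(prof[resp], ds.sites,
                                                k=config.spline_k,
                                                response_name=resp)
            loc = gradient.peak_location(fit)
            peaks.append({"response": resp,
                          "shape": "hump" if isinstance(loc, float) else loc,
                          "peak_elevation": loc if isinstance(loc, float) else np.nan,
                          "edf": fit.edf})
            p = out / f"smooth_{resp}.csv"
            fit.grid.to_csv(p, index=False, float_format=fmt)
            paths[f"smooth_{resp}"] = p
        cvi_fit = gradient.fit_cvi_glm(prof["CVI"], ds.sites, degree=2)
        p = out / "cvi_glm_curve.csv"
        cvi_fit.grid.to_csv(p, index=False, float_format=fmt)
        paths["cvi_glm_curve"] = p
        p = out / "gradient_peaks.csv"
        pd.DataFrame(peaks).to_csv(p, index=False, float_format=fmt)
        paths["gradient_peaks"] = p
        logger.info("stage gradient done in %.2fs", time.perf_counter() - t)

        t = _stage("drivers")
        env = ds.sites.environment()
        retained, removed = drivers.stepwise_vif_filter(env, config.vif_threshold)
        removal_log = pd.DataFrame(removed, columns=["predictor", "vif_at_removal"])
        p = out / "vif_removals.csv"
        removal_log.to_csv(p, index=False, float_format=fmt)
        paths["vif_removals"] = p
        for resp in DRIVER_RESPONSES:
            y = prof[resp]
            ok = y.notna()
            recs = drivers.all_subsets_fit(y[ok], retained.loc[ok],
                                           ds.sites.sites.loc[ok, "river_id"].to_numpy())
            avg = drivers.average_top_set(recs, delta=config.delta_aicc)
            tab = avg.table[["Estimate", "SE", "p", "importance"]].copy()
            tab.insert(0, "response", resp)
            p = out / f"drivers_{resp}.csv"
            tab.to_csv(p, index_label="term", float_format=fmt)
            paths[f"drivers_{resp}"] = p
        logger.info("stage drivers done in %.2fs", time.perf_counter() - t)

        t = _stage("manifest")
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": _versions(),
            "outputs": sorted(str(v.name) for v in paths.values()),
            "warnings": collector.messages,
        }
        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = p
        logger.info("full run done in %.2fs", time.perf_counter() - t_run)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)
    return paths
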