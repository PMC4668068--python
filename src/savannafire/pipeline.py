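"""One-command orchestration: simulate or ingest a fire history, compute all
metrics over successive assessment windows, score thresholds, estimate
credits, and write a consolidated CSV report bundle with a run manifest.

The pipeline is a pure composition of the stage functions — every stage
output is re-derivable by the corresponding stage CLI from the same
intermediate files — and is byte-deterministic given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .carbon import (
    EmissionParams,
    scenario_abatement_credits,
    seasonal_emissions,
    total_credits,
)
from .geodata import read_history, rasterize_units, write_history
from .grid import FireHistory, GridGeometry, LandscapeUnits, Unit
from .patches import DEFAULT_BIN_EDGES_KM2, patch_stats, patch_table, size_class_distribution
from .regime import AssessmentWindow, long_unburnt_proportion, seasonal_frequency
from .simulate import generate_history, regime_presets, synthetic_units
from .thresholds import assess, default_thresholds, load_thresholds

logger = logging.getLogger("savannafire")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML/JSON."""

    site: str = "synthetic"
    # input: either a simulation preset or a raster directory
    preset: str | None = "walfa_post"
    history_dir: str | None = None
    units_path: str | None = None  # GeoJSON; None -> synthetic lowland/upland split
    upland_fraction: float = 0.25
    grid_size: int = 200
    start_year: int = 2000
    n_windows: int = 3
    window_length: int = 5
    bins_km2: tuple[float, ...] = DEFAULT_BIN_EDGES_KM2
    thresholds_path: str | None = None
    carbon: dict[str, float] = field(
        default_factory=lambda: {
            "f_lds": 1.0,
            "eds_ratio": 0.5,
            "reduction_fraction": 0.38,
            "fcwf_rate_per_ha": 0.0,
            "tree_rate_per_ha": 0.0,
            "cv": 0.16,
        }
    )
    out_dir: str = "firemetrics_out"
    seed: int = 0
    log_level: str = "INFO"
    save_history: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    @property
    def n_years(self) -> int:
        return self.n_windows * self.window_length

    def windows(self) -> list[AssessmentWindow]:
        return [
            AssessmentWindow(self.start_year + i * self.window_length, self.window_length)
            for i in range(self.n_windows)
        ]

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig) -> tuple[FireHistory, LandscapeUnits]:
    if cfg.history_dir:
        history = read_history(cfg.history_dir)
        grid = history.grid
        units = (
            rasterize_units(cfg.units_path, grid)
            if cfg.units_path
            else synthetic_units(grid, cfg.upland_fraction)
        )
        return history, units
    presets = regime_presets()
    if cfg.preset not in presets:
        raise ValueError(f"unknown preset {cfg.preset!r}; available: {sorted(presets)}")
    grid = GridGeometry(cfg.grid_size, cfg.grid_size)
    units = (
        rasterize_units(cfg.units_path, grid)
        if cfg.units_path
        else synthetic_units(grid, cfg.upland_fraction)
    )
    history = generate_history(
        grid, units, presets[cfg.preset], cfg.n_years, seed=cfg.seed, start_year=cfg.start_year
    )
    return history, units


def _metrics_frame(
    history: FireHistory, units: LandscapeUnits, cfg: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for window in cfg.windows():
        freq = seasonal_frequency(history, units, window)
        unburnt = long_unburnt_proportion(history, units, window.end_year)
        for unit in units.present_units():
            f, u = freq[unit], unburnt[unit]
            for season in ("EDS", "LDS", "ANNUAL"):
                rows.append(
                    {
                        "site": cfg.site,
                        "unit": unit.value,
                        "window": window.label(),
                        "season": season,
                        "mean_frequency": f.mean[season],
                        "sem": f.sem[season],
                        "prop_unburnt_ge3": u.proportion_unburnt_ge3,
                        "prop_unburnt_ge5": u.proportion_unburnt_ge5,
                    }
                )
    return pd.DataFrame(rows)


def _patches_frame(
    history: FireHistory, units: LandscapeUnits, cfg: PipelineConfig
) -> pd.DataFrame:
    rows = []
    for window in cfg.windows():
        for scope in ("EDS", "LDS", "ANNUAL"):
            ps = patch_stats(history, units, window, scope)
            dist = size_class_distribution(history, units, window, scope, cfg.bins_km2)
            for unit in units.present_units():
                row = {
                    "site": cfg.site,
                    "unit": unit.value,
                    "window": window.label(),
                    "scope": scope,
                    "mean_patch_size_km2": ps.mean_patch_size_km2,
                    "sem_patch_size_km2": ps.sem_patch_size_km2,
                    "mean_annual_count": ps.mean_annual_count,
                    "sem_annual_count": ps.sem_annual_count,
                    "zero_patch_years": ps.zero_patch_years,
                }
                for label, m, s in zip(dist.bin_labels, dist.mean[unit], dist.sem[unit]):
                    row[f"prop_{label}"] = m
                    row[f"sem_{label}"] = s
                rows.append(row)
    return pd.DataFrame(rows)


def _compliance_frame(metrics: pd.DataFrame, patches: pd.DataFrame, cfg: PipelineConfig):
    rules = load_thresholds(cfg.thresholds_path) if cfg.thresholds_path else default_thresholds()
    frames = []
    for window_label in metrics["window"].unique():
        mw = metrics[metrics["window"] == window_label]
        pw = patches[(patches["window"] == window_label) & (patches["scope"] == "ANNUAL")]
        per_unit: dict[Unit, dict[str, float]] = {}
        for unit_name in mw["unit"].unique():
            mu = mw[mw["unit"] == unit_name]
            annual = mu[mu["season"] == "ANNUAL"].iloc[0]
            lds = mu[mu["season"] == "LDS"].iloc[0]
            obs = {
                "annual_frequency": annual["mean_frequency"],
                "lds_frequency": lds["mean_frequency"],
                "prop_unburnt_ge3": annual["prop_unburnt_ge3"],
            }
            prow = pw[pw["unit"] == unit_name]
            if len(prow):
                mps = prow.iloc[0]["mean_patch_size_km2"]
                if prow.iloc[0]["mean_annual_count"] == 0:
                    mps = 0.0  # fire-free window: no patches, trivially compliant
                obs["mean_patch_size"] = mps
            per_unit[Unit(unit_name)] = obs
        frames.append(assess(per_unit, rules, site=cfg.site, window=window_label))
    return pd.concat(frames, ignore_index=True)


def _credits_frame(
    history: FireHistory, units: LandscapeUnits, cfg: PipelineConfig
) -> pd.DataFrame:
    c = cfg.carbon
    eparams = EmissionParams(
        f_lds=c.get("f_lds", 1.0),
        eds_ratio=c.get("eds_ratio", 0.5),
        cv=c.get("cv", 0.16),
    )
    pix_ha = history.grid.pixel_area_ha
    rows = []
    for unit in units.present_units():
        umask = units.unit_mask(unit)
        area_ha = umask.sum() * pix_ha
        yearly = [
            (history.eds[i][umask].sum() * pix_ha, history.lds[i][umask].sum() * pix_ha)
            for i in range(history.n_years)
        ]
        baseline_em = sum(seasonal_emissions(e, l, eparams) for e, l in yearly) / len(yearly)
        abatement = scenario_abatement_credits(baseline_em, c.get("reduction_fraction", 0.38))
        fcwf = area_ha * c.get("fcwf_rate_per_ha", 0.0)
        tree = area_ha * c.get("tree_rate_per_ha", 0.0)
        est = total_credits(abatement, fcwf, tree, cfg.site, unit.value, area_ha, cv=eparams.cv)
        lo, hi = est.interval
        rows.append(
            {
                "site": cfg.site,
                "unit": unit.value,
                "area_ha": area_ha,
                "baseline_emissions_tco2e_y": baseline_em,
                "abatement_credits": est.abatement_credits,
                "fcwf_credits": est.fcwf_credits,
                "tree_credits": est.tree_credits,
                "total_credits": est.total_credits,
                "total_low": lo,
                "total_high": hi,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns the output paths.

    Any stage failure aborts with the stage name in the exception and removes
    partial outputs from this run.
    """
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "inputs"
    try:
        history, units = _load_inputs(cfg)
        if cfg.save_history:
            write_history(history, out_dir / "history")

        outputs: dict[str, pd.DataFrame] = {}
        stage = "metrics"
        outputs["metrics"] = _metrics_frame(history, units, cfg)
        stage = "patches"
        outputs["patches"] = _patches_frame(history, units, cfg)
        outputs["patch_table"] = patch_table(history, units)
        stage = "thresholds"
        outputs["compliance"] = _compliance_frame(outputs["metrics"], outputs["patches"], cfg)
        stage = "credits"
        outputs["credits"] = _credits_frame(history, units, cfg)

        stage = "write"
        paths: dict[str, Path] = {}
        for name, frame in outputs.items():
            p = out_dir / f"{name}.csv"
            frame.to_csv(p, index=False)
            written.append(p)
            paths[name] = p
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": json.loads(cfg.canonical()),
            "rows": {name: int(len(frame)) for name, frame in outputs.items()},
        }
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = mpath
        return paths
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
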