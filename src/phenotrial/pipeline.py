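"""End-to-end pipeline: simulate -> extract -> index -> traits -> analyze.

A run is driven by a :class:`RunConfig` (constructed in code or loaded from
a YAML file), executes the stages in dependency order under one root seed
(fanned out to fixed per-stage offsets so stages can be toggled without
perturbing each other), and writes every stage product plus a resolved
config copy and a log into the output directory.  Re-running with the same
config reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aux_traits import plot_mean_temperature
from .image_io import read_ms_cube, read_plot_map, read_rgb, read_thermal
from .ms_indexes import INDEX_NAMES, MSIndexParams, plot_ms_indexes
from .rgb_indexes import compute_rgb_indexes
from .synthetic import BAND_CENTRES, SceneSpec, TrialDesign, TrialEffects, simulate_trial
from .trial_stats import factorial_anova, stepwise_yield_model, yield_correlations

__all__ = ["RunConfig", "run_pipeline", "extract_rgb_indexes", "extract_ms_indexes", "extract_thermal_means", "assemble_trial_table", "analyze_trial"]

logger = logging.getLogger(__name__)

RGB_CSV_COLUMNS = [
    "plot_id", "intensity", "hue", "saturation", "lightness",
    "a_star", "b_star", "u_star", "v_star", "ga", "gga", "csi",
]

# per-stage seed offsets (root seed + offset, kept below 2**31)
_STAGE_OFFSETS = {"simulate": 0}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "phenotrial_run"
    n_hybrids: int = 8
    n_reps: int = 3
    effects: TrialEffects = field(default_factory=TrialEffects)
    scene: SceneSpec = field(default_factory=SceneSpec)
    ms_params: MSIndexParams = field(default_factory=MSIndexParams)
    stages: tuple[str, ...] = ("simulate", "extract", "analyze")
    anova_traits: tuple[str, ...] = ("grain_yield", "biomass", "harvest_index", "plot_temperature")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, klass in (("effects", TrialEffects), ("scene", SceneSpec), ("ms_params", MSIndexParams)):
            if isinstance(raw.get(key), dict):
                sub = dict(raw[key])
                for tup in ("residue_range", "rgb_shape", "ms_shape", "band_centres"):
                    if tup in sub and isinstance(sub[tup], list):
                        sub[tup] = tuple(sub[tup])
                raw[key] = klass(**sub)
        for tup in ("stages", "anova_traits"):
            if isinstance(raw.get(tup), list):
                raw[tup] = tuple(raw[tup])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ms_params"].pop("band_map", None)  # not YAML-friendly, never overridden per run
        return d


def extract_rgb_indexes(rgb_dir, plot_map: pd.DataFrame, intensity_mode: str = "mean") -> pd.DataFrame:
    """Per-plot RGB index table from a directory of {plot_id}.png|.jpg images."""
    rgb_dir = Path(rgb_dir)
    rows = []
    for plot_id in plot_map["plot_id"]:
        path = next((p for ext in (".png", ".jpg", ".jpeg") if (p := rgb_dir / f"{plot_id}{ext}").exists()), None)
        if path is None:
            raise FileNotFoundError(f"no RGB image for plot {plot_id} under {rgb_dir}")
        idx = compute_rgb_indexes(read_rgb(path), intensity_mode=intensity_mode)
        rows.append({"plot_id": plot_id, **idx.as_dict()})
    return pd.DataFrame(rows)[RGB_CSV_COLUMNS]


def extract_ms_indexes(ms_dir, plot_map: pd.DataFrame, params: MSIndexParams | None = None,
                       modes: tuple[str, ...] = ("plot", "vegetation"),
                       band_centres=BAND_CENTRES) -> pd.DataFrame:
    """Long-format multispectral index table (one row per plot x mode)."""
    params = params or MSIndexParams()
    ms_dir = Path(ms_dir)
    rows = []
    for plot_id in plot_map["plot_id"]:
        cube = read_ms_cube(ms_dir / f"{plot_id}.tif", band_centres)
        for mode in modes:
            s = plot_ms_indexes(cube, params, mode=mode)
            d = s.as_dict()
            rows.append({"plot_id": plot_id, "mode": mode, "vegetation_cover": d["vegetation_cover"],
                         **{k: d[k] for k in INDEX_NAMES}, "n_pixels_used": d["n_pixels_used"]})
    return pd.DataFrame(rows)


def extract_thermal_means(thermal_dir, plot_map: pd.DataFrame) -> pd.DataFrame:
    """Whole-plot mean temperature per plot from {plot_id}.tif rasters."""
    thermal_dir = Path(thermal_dir)
    rows = [
        {"plot_id": plot_id, "plot_temperature": plot_mean_temperature(read_thermal(thermal_dir / f"{plot_id}.tif"))}
        for plot_id in plot_map["plot_id"]
    ]
    return pd.DataFrame(rows)


def assemble_trial_table(plot_map: pd.DataFrame, rgb: pd.DataFrame | None = None,
                         ms: pd.DataFrame | None = None, thermal: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge stage outputs into the plot x trait matrix for the statistics stage.

    Multispectral indexes appear twice with ``_plot`` and ``_veg`` suffixes
    for whole-plot and vegetation-masked measurements.
    """
    table = plot_map.copy()
    if rgb is not None:
        table = table.merge(rgb, on="plot_id", how="left", validate="1:1")
    if ms is not None:
        for mode, suffix in (("plot", "_plot"), ("vegetation", "_veg")):
            sub = ms[ms["mode"] == mode].drop(columns=["mode", "n_pixels_used"])
            if sub.empty:
                continue
            if mode == "vegetation":
                sub = sub.drop(columns=["vegetation_cover"])
            sub = sub.rename(columns={c: f"{c}{suffix}" for c in sub.columns if c not in ("plot_id", "vegetation_cover")})
            table = table.merge(sub, on="plot_id", how="left", validate="1:1")
    if thermal is not None:
        table = table.merge(thermal, on="plot_id", how="left", validate="1:1")
    return table


def analyze_trial(table: pd.DataFrame, out_dir, anova_traits=("grain_yield",),
                  candidate_traits: list[str] | None = None) -> dict:
    """Statistics stage: ANOVAs, correlation tables and stepwise models.

    Writes anova_<trait>.csv, correlations.csv, stepwise.csv and report.txt
    under ``out_dir``; returns the in-memory results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"anova": {}, "correlations": None, "stepwise": {}}
    report: list[str] = [f"phenotrial {__version__} trial analysis", ""]

    for trait in anova_traits:
        if trait not in table.columns:
            continue
        res = factorial_anova(table, trait)
        results["anova"][trait] = res
        flat = res.effects.reset_index().assign(trait=trait)
        flat.to_csv(out_dir / f"anova_{trait}.csv", index=False)
        report.append(f"ANOVA {trait}:")
        for eff, row in res.effects.iterrows():
            report.append(f"  {eff}: F={row['F']:.3f} p={row['p']:.3f}{row['stars']}")
        for _, row in res.cell_means.iterrows():
            if ":" not in str(row["effect"]):
                report.append(f"  {row['effect']}={row['level']}: {row['mean']:.3f} +/- {row['sem']:.3f} (n={int(row['n'])})")
        report.append("")

    if candidate_traits is None:
        skip = {"plot_id", "tillage", "density", "hybrid", "rep", "grain_yield", "biomass",
                "harvest_index", "roi_row0", "roi_col0", "roi_row1", "roi_col1", "n_pixels_used"}
        candidate_traits = [c for c in table.columns if c not in skip and pd.api.types.is_numeric_dtype(table[c])]

    corr = yield_correlations(table, candidate_traits)
    corr.to_csv(out_dir / "correlations.csv", index=False)
    results["correlations"] = corr

    step_rows = []
    for subset in ("CA", "CP", "LD", "HD"):
        col = "tillage" if subset in ("CA", "CP") else "density"
        sub = table[table[col] == subset]
        if sub.empty:
            continue
        model = stepwise_yield_model(sub, candidate_traits)
        results["stepwise"][subset] = model
        eq = " + ".join([f"{model.coefficients['intercept']:.3f}"] +
                        [f"{model.coefficients[p]:.3f}*{p}" for p in model.selected_predictors])
        report.append(f"stepwise [{subset}]: GY = {eq}")
        report.append(f"  R2={model.r_squared:.3f} RSE={model.rse:.3f} p={model.p_value:.3g} n={model.n}")
        for p in model.selected_predictors:
            step_rows.append({"subset": subset, "predictor": p, "coefficient": model.coefficients[p],
                              "variance_portion": model.variance_portions[p], "r_squared": model.r_squared,
                              "rse": model.rse, "p_value": model.p_value, "intercept": model.coefficients["intercept"],
                              "n": model.n})
    pd.DataFrame(step_rows).to_csv(out_dir / "stepwise.csv", index=False)
    (out_dir / "report.txt").write_text("\n".join(report) + "\n")
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage order: simulate (synthetic trial + images), extract (RGB,
    multispectral, thermal trait tables and the merged trial table),
    analyze (ANOVA / correlations / stepwise).  The resolved config and a
    run log are always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    log_lines = [f"phenotrial {__version__}", f"python {platform.python_version()}",
                 f"numpy {np.__version__}", f"seed {config.seed}", f"stages {','.join(config.stages)}"]

    sim_dir = out / "sim"
    if "simulate" in config.stages:
        design = TrialDesign(n_hybrids=config.n_hybrids, n_reps=config.n_reps, seed=config.seed)
        simulate_trial(sim_dir, design, config.effects, config.scene, seed=config.seed + _STAGE_OFFSETS["simulate"])
        log_lines.append(f"simulate: {design.n_plots} plots -> {sim_dir}")

    if "extract" in config.stages:
        if not (sim_dir / "plot_map.csv").exists():
            raise FileNotFoundError(f"extract stage needs {sim_dir / 'plot_map.csv'}; run simulate first")
        plot_map = read_plot_map(sim_dir / "plot_map.csv")
        rgb = extract_rgb_indexes(sim_dir / "rgb", plot_map)
        rgb.to_csv(out / "rgb_indexes.csv", index=False)
        ms = extract_ms_indexes(sim_dir / "ms", plot_map, config.ms_params, band_centres=config.scene.band_centres)
        ms.to_csv(out / "ms_indexes.csv", index=False)
        thermal = extract_thermal_means(sim_dir / "thermal", plot_map)
        thermal.to_csv(out / "aux_traits.csv", index=False)
        table = assemble_trial_table(plot_map, rgb, ms, thermal)
        table.to_csv(out / "trial_table.csv", index=False)
        log_lines.append(f"extract: {len(table)} plots, {table.shape[1]} columns")

    if "analyze" in config.stages:
        table_path = out / "trial_table.csv"
        if not table_path.exists():
            raise FileNotFoundError(f"analyze stage needs {table_path}; run extract first")
        table = pd.read_csv(table_path, dtype={"plot_id": str})
        analyze_trial(table, out / "analysis", anova_traits=config.anova_traits)
        log_lines.append("analyze: done")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
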