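"""Synthetic field-trial generator for the phenotyping pipeline.

Emulates a maize tillage trial contrasting conservation agriculture (CA:
no-till, soil covered by at least 30% crop-residue stover) against
conventional ploughing (CP: bare-soil background), crossed with two planting
densities and several hybrids in a randomized complete block design.  Every
plot receives hidden ground truth (canopy fraction, senescence, residue
cover, background brightness, yield) and can be rendered as co-consistent
RGB, 11-band multispectral and thermal plot images so each downstream stage
is verifiable against known truth.

Statistical structure of the stated world
-----------------------------------------
* grain yield = baseline + tillage effect (CA) + hybrid effect
  + slope x (canopy fraction - its per-tillage mean) + Gaussian noise,
  truncated at zero (truncations logged).  The canopy term is centred
  within tillage arm so the tillage effect parameter equals the total
  CA-CP contrast.
* canopy fraction is higher under CA on average, so greenness indexes
  (GA, GGA, plot-mode NDVI) come out higher under CA;
* the background brightness multiplier is far more variable under CA
  (heterogeneous weathered/shadowed stover) than under CP (uniform
  ploughed soil), which injects yield-independent noise into whole-plot
  reflectance indexes and weakens index-yield correlations in the CA arm -
  the masking rationale the pipeline exists to test.

Class assignment inside a plot is random pixel labelling (no spatial
texture): every downstream index is order-invariant over pixels.  Realized
class pixel counts match the requested fractions to within one pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import MultispectralCube, write_ms_cube, write_rgb, write_thermal

__all__ = [
    "BAND_CENTRES",
    "RGB_CLASS_COLOURS",
    "MS_CLASS_SPECTRA",
    "TrialDesign",
    "TrialEffects",
    "SceneSpec",
    "GroundTruth",
    "generate_design",
    "draw_ground_truth",
    "class_pixel_counts",
    "render_rgb_plot",
    "render_ms_plot",
    "render_thermal_plot",
    "simulate_trial",
    "child_rng",
]

logger = logging.getLogger(__name__)

TILLAGE_LEVELS = ("CA", "CP")
DENSITY_LEVELS = ("LD", "HD")

#: camera band centres, nm, ascending
BAND_CENTRES = (450, 550, 570, 670, 700, 720, 780, 840, 860, 900, 950)

#: reference sRGB colours (8-bit) per scene class.  Hues: green canopy
#: ~127 deg, senescent canopy ~66 deg (inside GA, outside GGA), soil ~25 deg,
#: residue straw ~47 deg (pale, outside GA) - so GA = canopy fraction and
#: GGA = green canopy fraction by construction.
RGB_CLASS_COLOURS = {
    "canopy_green": np.array([60.0, 140.0, 70.0]),
    "canopy_senescent": np.array([150.0, 160.0, 60.0]),
    "soil": np.array([120.0, 85.0, 60.0]),
    "residue": np.array([205.0, 190.0, 120.0]),
}

#: reference reflectance spectra over BAND_CENTRES.  Green canopy NDVI 0.82,
#: senescent canopy 0.56 (still above the 0.4 mask threshold with margin
#: >= 0.15), soil 0.16 and residue 0.15 (below threshold with margin
#: >= 0.15), so the NDVI mask separates canopy from background exactly at
#: zero noise and with wide margin at default noise.
MS_CLASS_SPECTRA = {
    "canopy_green": np.array([0.03, 0.08, 0.07, 0.05, 0.12, 0.25, 0.42, 0.50, 0.50, 0.49, 0.46]),
    "canopy_senescent": np.array([0.08, 0.20, 0.19, 0.13, 0.20, 0.28, 0.40, 0.46, 0.46, 0.45, 0.41]),
    "soil": np.array([0.10, 0.14, 0.15, 0.18, 0.19, 0.20, 0.22, 0.25, 0.25, 0.26, 0.26]),
    "residue": np.array([0.14, 0.19, 0.20, 0.22, 0.23, 0.24, 0.27, 0.30, 0.30, 0.31, 0.31]),
}

_CLASS_ORDER = ("canopy_green", "canopy_senescent", "soil", "residue")


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child generator for (seed, stage, item) keys."""
    return np.random.default_rng([int(seed), *[int(k) for k in keys]])


@dataclass(frozen=True)
class TrialDesign:
    """Factorial layout: 2 tillage x 2 density x hybrids x replicates."""

    n_hybrids: int = 8
    n_reps: int = 3
    seed: int = 0
    n_tillage: int = 2  # fixed: CA, CP
    n_density: int = 2  # fixed: LD, HD

    def __post_init__(self):
        if self.n_tillage != 2 or self.n_density != 2:
            raise ValueError("the trial contrasts exactly 2 tillage and 2 density levels")
        if self.n_hybrids < 1 or self.n_reps < 1:
            raise ValueError("need at least one hybrid and one replicate")

    @property
    def n_plots(self) -> int:
        return self.n_tillage * self.n_density * self.n_hybrids * self.n_reps

    @property
    def hybrids(self) -> tuple[str, ...]:
        return tuple(f"H{i + 1}" for i in range(self.n_hybrids))


@dataclass(frozen=True)
class TrialEffects:
    """Effect sizes and variance components of the generated trial.

    Yields in Mg/ha, temperatures in deg C, fractions dimensionless.  The
    defaults place the CP baseline at 2.42 Mg/ha with a +0.57 CA contrast
    (a realistic smallholder maize contrast), canopy fractions of ~0.55
    (CP) vs ~0.66 (CA), and a canopy-yield slope / residual noise mix that
    makes within-arm index-yield correlations land near 0.8 under CP.
    """

    baseline_yield: float = 2.42
    tillage_yield_effect: float = 0.57
    hybrid_sd: float = 0.25
    canopy_yield_slope: float = 4.0
    noise_sd: float = 0.30
    canopy_mean_cp: float = 0.55
    canopy_shift_ca: float = 0.11
    canopy_sd: float = 0.12
    senescent_mean: float = 0.12
    senescent_sd: float = 0.06
    residue_range: tuple[float, float] = (0.3, 0.9)
    background_brightness_sd_ca: float = 0.20
    background_brightness_sd_cp: float = 0.06
    canopy_temp_cp: float = 24.64
    canopy_temp_shift_ca: float = 0.38
    temp_noise_sd: float = 0.15
    harvest_index_mean: float = 0.47
    harvest_index_sd: float = 0.03

    def __post_init__(self):
        if self.noise_sd < 0 or self.hybrid_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not np.isfinite(self.canopy_yield_slope):
            raise ValueError("canopy_yield_slope must be finite")
        lo, hi = self.residue_range
        if not (0.3 <= lo <= hi <= 1.0):
            raise ValueError("CA residue fraction must stay within [0.3, 1] (FAO residue criterion)")


@dataclass(frozen=True)
class SceneSpec:
    """Rendered scene geometry and noise levels.

    The default RGB resolution matches a UAV plot crop (825 x 1210); the
    multispectral cube is strictly smaller in both dimensions, mirroring
    the resolution contrast between consumer RGB and multispectral array
    cameras.  Noise is i.i.d. Gaussian per channel/band, applied after
    class colours/spectra and clipped to the valid range.
    """

    rgb_shape: tuple[int, int] = (825, 1210)
    ms_shape: tuple[int, int] = (275, 403)
    band_centres: tuple[int, ...] = BAND_CENTRES
    pixel_noise_sd: float = 0.01  # reflectance units
    rgb_noise_sd: float = 2.0  # 8-bit counts
    thermal_noise_sd: float = 0.10  # deg C
    background_temp_offset: float = 5.0  # background warmer than canopy

    def __post_init__(self):
        if not (self.ms_shape[0] < self.rgb_shape[0] and self.ms_shape[1] < self.rgb_shape[1]):
            raise ValueError("ms_shape must be strictly smaller than rgb_shape in both dimensions")
        centres = tuple(int(w) for w in self.band_centres)
        if list(centres) != sorted(set(centres)):
            raise ValueError("band centres must be strictly increasing")
        object.__setattr__(self, "band_centres", centres)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden per-plot parameters behind the rendered images."""

    plot_id: str
    tillage: str
    canopy_fraction: float
    senescent_fraction: float
    residue_fraction: float
    soil_brightness: float
    true_yield_mean: float
    canopy_temperature: float

    def __post_init__(self):
        for name in ("canopy_fraction", "senescent_fraction", "residue_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.tillage == "CP" and self.residue_fraction != 0.0:
            raise ValueError("CP plots carry no residue")
        if self.tillage == "CA" and self.residue_fraction < 0.3:
            raise ValueError("CA plots require residue cover >= 0.30")


def generate_design(design: TrialDesign) -> pd.DataFrame:
    """Build the randomized design table.

    One row per plot with columns plot_id, tillage, density, hybrid, rep;
    hybrid order is randomized independently within every
    (tillage, density, rep) block.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for tillage in TILLAGE_LEVELS:
        for density in DENSITY_LEVELS:
            for rep in range(1, design.n_reps + 1):
                order = rng.permutation(design.n_hybrids)
                for h in order:
                    rows.append((tillage, density, design.hybrids[h], rep))
    df = pd.DataFrame(rows, columns=["tillage", "density", "hybrid", "rep"])
    df.insert(0, "plot_id", [f"P{i + 1:03d}" for i in range(len(df))])
    return df


def draw_ground_truth(
    design_table: pd.DataFrame,
    effects: TrialEffects | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-plot ground truth and realized agronomy for a design table.

    Returns the design columns plus canopy_fraction, senescent_fraction,
    residue_fraction, soil_brightness (background brightness multiplier),
    true_yield_mean, canopy_temperature, grain_yield, biomass and
    harvest_index.  Negative realized yields are truncated at zero and
    logged.  Deterministic given ``seed``.
    """
    effects = effects or TrialEffects()
    rng = child_rng(seed, 1)
    df = design_table.copy().reset_index(drop=True)
    n = len(df)
    is_ca = (df["tillage"] == "CA").to_numpy()

    hybrids = sorted(df["hybrid"].unique())
    hybrid_effect = dict(zip(hybrids, rng.normal(0.0, effects.hybrid_sd, len(hybrids)) if effects.hybrid_sd > 0 else np.zeros(len(hybrids))))

    cf_mean = effects.canopy_mean_cp + effects.canopy_shift_ca * is_ca
    canopy = np.clip(cf_mean + rng.normal(0.0, effects.canopy_sd, n), 0.02, 0.98)
    senescent = np.clip(rng.normal(effects.senescent_mean, effects.senescent_sd, n), 0.0, 1.0)
    lo, hi = effects.residue_range
    residue = np.where(is_ca, rng.uniform(lo, hi, n), 0.0)
    bg_sd = np.where(is_ca, effects.background_brightness_sd_ca, effects.background_brightness_sd_cp)
    brightness = np.clip(1.0 + rng.standard_normal(n) * bg_sd, 0.5, 1.2)

    true_mean = (
        effects.baseline_yield
        + effects.tillage_yield_effect * is_ca
        + df["hybrid"].map(hybrid_effect).to_numpy()
        + effects.canopy_yield_slope * (canopy - cf_mean)
    )
    grain = true_mean + (rng.normal(0.0, effects.noise_sd, n) if effects.noise_sd > 0 else 0.0)
    n_trunc = int(np.count_nonzero(grain < 0))
    if n_trunc:
        logger.warning("truncated %d negative generated yield(s) at 0", n_trunc)
    grain = np.maximum(grain, 0.0)

    hi_idx = np.clip(rng.normal(effects.harvest_index_mean, effects.harvest_index_sd, n), 0.2, 0.8)
    biomass = np.where(grain > 0, grain / hi_idx, 0.0)

    temp = (
        effects.canopy_temp_cp
        + effects.canopy_temp_shift_ca * is_ca
        + rng.normal(0.0, effects.temp_noise_sd, n)
    )

    out = df.copy()
    out["canopy_fraction"] = canopy
    out["senescent_fraction"] = senescent
    out["residue_fraction"] = residue
    out["soil_brightness"] = brightness
    out["true_yield_mean"] = true_mean
    out["canopy_temperature"] = temp
    out["grain_yield"] = grain
    out["biomass"] = biomass
    with np.errstate(divide="ignore", invalid="ignore"):
        out["harvest_index"] = np.where(biomass > 0, grain / biomass, np.nan)
    return out


def ground_truth_records(gt_table: pd.DataFrame) -> list[GroundTruth]:
    """Typed GroundTruth views of the generator's table rows."""
    return [
        GroundTruth(
            plot_id=str(r.plot_id),
            tillage=str(r.tillage),
            canopy_fraction=float(r.canopy_fraction),
            senescent_fraction=float(r.senescent_fraction),
            residue_fraction=float(r.residue_fraction),
            soil_brightness=float(r.soil_brightness),
            true_yield_mean=float(r.true_yield_mean),
            canopy_temperature=float(r.canopy_temperature),
        )
        for r in gt_table.itertuples()
    ]


def class_pixel_counts(n_pixels: int, canopy_fraction: float, senescent_fraction: float, residue_fraction: float) -> dict[str, int]:
    """Integer pixel counts per scene class.

    Canopy pixels are rounded from canopy_fraction x n, senescent canopy
    from senescent_fraction x canopy, residue from residue_fraction x
    background; every realized class fraction is within one pixel of the
    request and the counts sum exactly to ``n_pixels``.
    """
    if n_pixels <= 0:
        raise ValueError("a plot image needs at least one pixel")
    n_canopy = int(round(canopy_fraction * n_pixels))
    n_sen = int(round(senescent_fraction * n_canopy))
    n_bg = n_pixels - n_canopy
    n_res = int(round(residue_fraction * n_bg))
    return {
        "canopy_green": n_canopy - n_sen,
        "canopy_senescent": n_sen,
        "soil": n_bg - n_res,
        "residue": n_res,
    }


def _class_labels(gt, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    counts = class_pixel_counts(
        shape[0] * shape[1], gt.canopy_fraction, gt.senescent_fraction, gt.residue_fraction
    )
    labels = np.repeat(np.arange(4), [counts[c] for c in _CLASS_ORDER])
    return rng.permutation(labels).reshape(shape)


def render_rgb_plot(gt: GroundTruth, spec: SceneSpec | None = None, seed: int = 0) -> np.ndarray:
    """Render one plot as an 8-bit RGB image.

    Pixels are partitioned into green canopy, senescent canopy, soil and
    residue classes in the ground-truth proportions (random spatial
    arrangement); background classes are scaled by the plot's background
    brightness multiplier (hue-preserving); Gaussian channel noise is added
    and the result clipped to [0, 255].
    """
    spec = spec or SceneSpec()
    rng = child_rng(seed, 2)
    labels = _class_labels(gt, spec.rgb_shape, rng)
    palette = np.stack([RGB_CLASS_COLOURS[c] for c in _CLASS_ORDER])
    palette = palette.copy()
    palette[2:] *= gt.soil_brightness  # soil and residue only
    img = palette[labels]
    if spec.rgb_noise_sd > 0:
        img = img + rng.normal(0.0, spec.rgb_noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_ms_plot(gt: GroundTruth, spec: SceneSpec | None = None, seed: int = 0) -> MultispectralCube:
    """Render one plot as an 11-band reflectance cube.

    Same class fractions as the RGB rendering of the plot but an
    independent pixel arrangement (the two cameras are not co-registered);
    reflectance noise is added per band and clipped to [0, 1].
    """
    spec = spec or SceneSpec()
    if tuple(spec.band_centres) != BAND_CENTRES:
        raise ValueError("class spectra are defined on the default 11 band centres")
    rng = child_rng(seed, 3)
    labels = _class_labels(gt, spec.ms_shape, rng)
    spectra = np.stack([MS_CLASS_SPECTRA[c] for c in _CLASS_ORDER]).astype(np.float64)
    spectra = spectra.copy()
    spectra[2:] *= gt.soil_brightness
    cube = spectra[labels]  # (rows, cols, bands)
    if spec.pixel_noise_sd > 0:
        cube = cube + rng.normal(0.0, spec.pixel_noise_sd, cube.shape)
    cube = np.clip(cube, 0.0, 1.0).transpose(2, 0, 1)
    return MultispectralCube(cube.astype(np.float32), spec.band_centres)


def render_thermal_plot(gt: GroundTruth, spec: SceneSpec | None = None, seed: int = 0) -> np.ndarray:
    """Render one plot as a thermal raster in degrees Celsius.

    Canopy pixels sit at the plot's canopy temperature; background pixels
    are warmer by ``spec.background_temp_offset`` (dry soil and residue
    heat above the transpiring canopy); Gaussian noise added.
    """
    spec = spec or SceneSpec()
    if not np.isfinite(gt.canopy_temperature):
        raise ValueError("canopy temperature must be finite")
    rng = child_rng(seed, 4)
    labels = _class_labels(gt, spec.ms_shape, rng)
    temps = np.array([0.0, 0.0, spec.background_temp_offset, spec.background_temp_offset])
    raster = gt.canopy_temperature + temps[labels]
    if spec.thermal_noise_sd > 0:
        raster = raster + rng.normal(0.0, spec.thermal_noise_sd, raster.shape)
    return raster.astype(np.float32)


def simulate_trial(
    out_dir,
    design: TrialDesign | None = None,
    effects: TrialEffects | None = None,
    spec: SceneSpec | None = None,
    seed: int = 0,
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate and write a complete synthetic trial.

    Writes ``plot_map.csv`` (design + agronomy + full-frame ROIs),
    ``ground_truth.csv`` and, when ``write_images``, per-plot files under
    ``rgb/``, ``ms/`` and ``thermal/``.  Returns the ground-truth table.
    Fully deterministic given ``seed``.
    """
    design = design or TrialDesign()
    effects = effects or TrialEffects()
    spec = spec or SceneSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = draw_ground_truth(generate_design(design), effects, seed=seed)

    if write_images:
        for i, gt in enumerate(ground_truth_records(table)):
            write_rgb(render_rgb_plot(gt, spec, seed=int(seed) + 10 * i + 1), out_dir / "rgb" / f"{gt.plot_id}.png")
            write_ms_cube(render_ms_plot(gt, spec, seed=int(seed) + 10 * i + 2), out_dir / "ms" / f"{gt.plot_id}.tif")
            write_thermal(render_thermal_plot(gt, spec, seed=int(seed) + 10 * i + 3), out_dir / "thermal" / f"{gt.plot_id}.tif")

    plot_map = table[["plot_id", "tillage", "density", "hybrid", "rep", "grain_yield", "biomass", "harvest_index"]].copy()
    plot_map["roi_row0"] = 0
    plot_map["roi_col0"] = 0
    plot_map["roi_row1"] = spec.rgb_shape[0]
    plot_map["roi_col1"] = spec.rgb_shape[1]
    plot_map.to_csv(out_dir / "plot_map.csv", index=False)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table
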