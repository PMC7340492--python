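"""Multispectral vegetation indexes with optional NDVI soil masking.

Thirteen narrow-band indexes are computed per plot from an 11-band
reflectance cube (band centres 450-950 nm) in one of two aggregation modes:

* ``plot`` - indexes computed from the per-band mean reflectance over every
  pixel of the plot (whole-plot measurement);
* ``vegetation`` - per-band means restricted to pixels passing the NDVI
  soil mask (0.4 <= NDVI <= 1 by default), so soil and crop-residue
  background are excluded.

Vegetation cover (percent) is the complement of the soil mask.

Formula notes
-------------
The canonical published forms are used.  Several frequently mis-printed
variants circulate; for RDVI, PRI and SAVI an ``as_printed`` switch
reproduces the degenerate printed forms (RDVI collapsing to NDVI, PRI
identically 1, SAVI without the (1+L) scaling) for sensitivity checks.
PRI here substitutes the 550 nm band for the original 531 nm band, which
the 11-filter camera does not carry; WBI likewise uses 950/900 nm in place
of 970/900 nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .image_io import MultispectralCube

__all__ = [
    "MSIndexParams",
    "MSIndexSet",
    "INDEX_NAMES",
    "pixel_indexes",
    "spectral_indexes",
    "ndvi_mask",
    "vegetation_cover",
    "plot_ms_indexes",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = (
    "ndvi",
    "savi",
    "osavi",
    "rdvi",
    "evi",
    "pri",
    "mcari",
    "cci",
    "tcari",
    "tcari_osavi",
    "ari2",
    "cri2",
    "wbi",
)

#: wavelengths (nm) each index reads; all must exist among the cube's band centres
BAND_MAP: dict[str, tuple[int, ...]] = {
    "ndvi": (840, 670),
    "savi": (840, 670),
    "osavi": (780, 670),
    "rdvi": (840, 670),
    "evi": (840, 670, 450),
    "pri": (550, 570),
    "mcari": (700, 670, 550),
    "cci": (550, 670),
    "tcari": (700, 670, 550),
    "tcari_osavi": (700, 670, 550, 780),
    "ari2": (840, 550, 700),
    "cri2": (550, 700),
    "wbi": (950, 900),
}


@dataclass(frozen=True)
class MSIndexParams:
    """Index and soil-mask parameters.

    ``savi_l`` is the soil-adjustment factor (0.5 for intermediate
    vegetation); ``osavi_c`` the OSAVI constant 0.16; the mask keeps pixels
    with NDVI in [``ndvi_mask_low``, ``ndvi_mask_high``].
    """

    savi_l: float = 0.5
    osavi_c: float = 0.16
    ndvi_mask_low: float = 0.4
    ndvi_mask_high: float = 1.0
    as_printed: bool = False
    band_map: Mapping[str, tuple[int, ...]] = field(default_factory=lambda: dict(BAND_MAP))

    def __post_init__(self):
        if not (0.0 <= self.ndvi_mask_low < self.ndvi_mask_high <= 1.0):
            raise ValueError(
                f"require 0 <= ndvi_mask_low < ndvi_mask_high <= 1, got "
                f"[{self.ndvi_mask_low}, {self.ndvi_mask_high}]"
            )


@dataclass(frozen=True)
class MSIndexSet:
    """Per-plot multispectral index values in one aggregation mode."""

    mode: str
    ndvi: float
    savi: float
    osavi: float
    rdvi: float
    evi: float
    pri: float
    mcari: float
    cci: float
    tcari: float
    tcari_osavi: float
    ari2: float
    cri2: float
    wbi: float
    vegetation_cover: float
    n_pixels_used: int

    def as_dict(self) -> dict:
        return asdict(self)


def _safe_div(num, den):
    """Elementwise num/den with NaN (missing) where den == 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def spectral_indexes(bands: Mapping[int, np.ndarray | float], params: MSIndexParams | None = None) -> dict[str, np.ndarray | float]:
    """All thirteen indexes from reflectance keyed by band centre (nm).

    Values may be scalars or equally-shaped arrays (vectorized).  A zero
    denominator yields NaN for that element/index, never an exception.
    """
    params = params or MSIndexParams()
    need = {w for waves in params.band_map.values() for w in waves}
    missing = sorted(need - set(bands))
    if missing:
        raise KeyError(f"required band centres missing from spectrum: {missing} nm")

    b = {w: np.asarray(bands[w], dtype=float) for w in need}
    if any((v < 0).any() for v in b.values()):
        raise ValueError("reflectance must be non-negative")
    L, c = params.savi_l, params.osavi_c

    out: dict[str, np.ndarray | float] = {}
    out["ndvi"] = _safe_div(b[840] - b[670], b[840] + b[670])
    if params.as_printed:
        out["savi"] = _safe_div(b[840] - b[670], b[840] + b[670] + L)
        out["rdvi"] = _safe_div(b[840] - b[670], b[840] + b[670])
        out["pri"] = np.where(np.isfinite(b[550]), 1.0, np.nan)  # printed denominator == numerator
    else:
        out["savi"] = (1.0 + L) * _safe_div(b[840] - b[670], b[840] + b[670] + L)
        with np.errstate(invalid="ignore"):
            out["rdvi"] = _safe_div(b[840] - b[670], np.sqrt(b[840] + b[670]))
        out["pri"] = _safe_div(b[550] - b[570], b[550] + b[570])
    out["osavi"] = (1.0 + c) * _safe_div(b[780] - b[670], b[780] + b[670] + c)
    out["evi"] = 2.5 * _safe_div(b[840] - b[670], b[840] + 6.0 * b[670] - 7.5 * b[450] + 1.0)
    ratio_700_670 = _safe_div(b[700], b[670])
    out["mcari"] = ((b[700] - b[670]) - 0.2 * (b[700] - b[550])) * ratio_700_670
    out["cci"] = _safe_div(b[550] - b[670], b[550] + b[670])
    out["tcari"] = 3.0 * ((b[700] - b[670]) - 0.2 * (b[700] - b[550]) * ratio_700_670)
    out["tcari_osavi"] = _safe_div(out["tcari"], out["osavi"])
    inv_550 = _safe_div(1.0, b[550])
    inv_700 = _safe_div(1.0, b[700])
    out["cri2"] = inv_550 - inv_700
    out["ari2"] = b[840] * out["cri2"]
    out["wbi"] = _safe_div(b[950], b[900])
    return out


def pixel_indexes(spectrum: Mapping[int, float], params: MSIndexParams | None = None) -> dict[str, float]:
    """Index values for a single-pixel spectrum (band centre nm -> reflectance)."""
    return {k: float(v) for k, v in spectral_indexes(spectrum, params).items()}


def ndvi_mask(cube: MultispectralCube, params: MSIndexParams | None = None) -> np.ndarray:
    """Boolean vegetation mask: True where mask_low <= NDVI <= mask_high.

    Pixels with NDVI below the lower threshold correspond to bare ground /
    residue background and are masked out.  An all-false mask is allowed.
    """
    params = params or MSIndexParams()
    ndvi = _safe_div(cube.band(840) - cube.band(670), cube.band(840) + cube.band(670))
    with np.errstate(invalid="ignore"):
        return (ndvi >= params.ndvi_mask_low) & (ndvi <= params.ndvi_mask_high)


def vegetation_cover(mask: np.ndarray) -> float:
    """Percent of plot pixels classified as vegetation by the NDVI mask."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("vegetation cover of an empty raster is undefined")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def plot_ms_indexes(
    cube: MultispectralCube,
    params: MSIndexParams | None = None,
    mode: str = "plot",
    aggregation: str = "mean_reflectance",
) -> MSIndexSet:
    """Aggregate a plot cube into one MSIndexSet.

    ``mode='plot'`` uses every pixel; ``mode='vegetation'`` only pixels
    passing the NDVI mask.  ``aggregation='mean_reflectance'`` (default)
    averages reflectance per band first and applies the index formulas to
    the mean spectrum; ``'per_pixel'`` computes indexes per pixel and
    averages them (sensitivity-check option; the two differ for ratio
    indexes).  An empty vegetation mask yields all-NaN indexes with a
    logged warning rather than an error.
    """
    params = params or MSIndexParams()
    if mode not in ("plot", "vegetation"):
        raise ValueError(f"mode must be 'plot' or 'vegetation', got {mode!r}")
    if aggregation not in ("mean_reflectance", "per_pixel"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if cube.bands.size == 0:
        raise ValueError("cannot aggregate an empty cube")

    mask = ndvi_mask(cube, params)
    cover = vegetation_cover(mask)
    sel = mask if mode == "vegetation" else np.ones_like(mask)
    n_used = int(np.count_nonzero(sel))

    if n_used == 0:
        logger.warning("empty NDVI mask: vegetation-mode indexes reported as missing")
        values = {name: float("nan") for name in INDEX_NAMES}
    else:
        pix = {w: cube.band(w)[sel] for w in cube.band_centres}
        if aggregation == "mean_reflectance":
            spectrum = {w: float(v.mean()) for w, v in pix.items()}
            values = {k: float(v) for k, v in spectral_indexes(spectrum, params).items()}
        else:
            per_pixel = spectral_indexes(pix, params)
            values = {k: float(np.nanmean(v)) if np.isfinite(v).any() else float("nan") for k, v in per_pixel.items()}

    return MSIndexSet(mode=mode, vegetation_cover=cover, n_pixels_used=n_used, **values)
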