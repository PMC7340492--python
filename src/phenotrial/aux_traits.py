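"""Auxiliary plot traits: thermal means, isotope delta notation, C/N ratio.

Thermal rasters arrive either already in degrees Celsius (32-bit float) or
as raw integer counts encoding Kelvin times a scale factor; the nominal
scale of 10,000 counts per Kelvin is configurable because it exceeds the
16-bit integer range at ambient temperatures and real exports use other
scalings.  Plot temperature is the arithmetic mean over the whole plot ROI
with no vegetation masking.
"""

from __future__ import annotations

import numpy as np

from .image_io import crop_roi

__all__ = [
    "R_VPDB_13C",
    "R_AIR_15N",
    "delta_notation",
    "delta_to_ratio",
    "thermal_raw_to_celsius",
    "plot_mean_temperature",
    "c_n_ratio",
]

#: 13C/12C of the Vienna Pee Dee Belemnite carbonate standard
R_VPDB_13C = 0.0112372
#: 15N/14N of atmospheric N2, the nitrogen delta reference
R_AIR_15N = 0.0036765

_ZERO_C_IN_K = 273.15


def delta_notation(r_sample, r_standard):
    """Isotopic composition in per-mil: delta = (Rsample/Rstandard - 1) * 1000.

    Used for d13C (standard VPDB) and d15N (standard atmospheric N2).
    Vectorized over array inputs; the standard ratio must be positive.
    """
    r_standard = np.asarray(r_standard, dtype=float)
    if (r_standard <= 0).any():
        raise ValueError("the standard isotope ratio must be strictly positive")
    out = (np.asarray(r_sample, dtype=float) / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out

def delta_to_ratio(delta, r_standard):
    """Inverse of :func:`delta_notation`: Rsample = Rstandard * (1 + delta/1000)."""
    r_standard = np.asarray(r_standard, dtype=float)
    if (r_standard <= 0).any():
        raise ValueError("the standard isotope ratio must be strictly positive")
    out = r_standard * (1.0 + np.asarray(delta, dtype=float) / 1000.0)
    return float(out) if out.ndim == 0 else out


def thermal_raw_to_celsius(raw, scale: float = 10000.0):
    """Convert raw thermal counts (Kelvin x scale) to degrees Celsius."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw thermal counts must be non-negative")
    out = raw / scale - _ZERO_C_IN_K
    return float(out) if out.ndim == 0 else out


def plot_mean_temperature(raster: np.ndarray, roi=None) -> float:
    """Whole-plot mean temperature (deg C) over an optional half-open ROI."""
    raster = np.asarray(raster, dtype=float)
    if roi is not None:
        raster = crop_roi(raster, roi)
    if raster.size == 0:
        raise ValueError("cannot average an empty thermal ROI")
    return float(raster.mean())


def c_n_ratio(percent_c, percent_n):
    """Leaf C/N mass ratio from elemental percentages; NaN where %N = 0."""
    pc = np.asarray(percent_c, dtype=float)
    pn = np.asarray(percent_n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pn > 0, pc / np.where(pn > 0, pn, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out
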