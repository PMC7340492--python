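"""RGB colour-space statistics and canopy-fraction indexes for plot images.

Implements the Breedpix-style set of plot descriptors: HSI components
(hexagonal hue, saturation, intensity), CIELab / CIELuv chromaticity means,
and the hue-threshold canopy indexes Green Area (GA), Greener Area (GGA) and
the Crop Senescence Index (CSI).

Conventions
-----------
* Input images are 8-bit sRGB (divided by 255) or floats already in [0, 1].
* Colour pipeline is fixed: sRGB gamma -> linear RGB -> XYZ (D65, 2deg
  observer) -> CIELab / CIELuv with the D65 white point.  No camera-specific
  calibration is applied.
* Hue is the HSV hexagonal hue in degrees [0, 360).  Achromatic pixels
  (r = g = b) have undefined hue: they are excluded from the circular hue
  mean and from the GA/GGA numerators but always count in the denominators.
* GA counts pixels with hue in [60, 180) degrees, GGA in [80, 180) degrees
  (half-open intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RGBIndexSet",
    "srgb_to_hsi",
    "srgb_to_lab_luv",
    "compute_rgb_indexes",
    "csi",
    "average_index_sets",
]

GA_HUE_RANGE = (60.0, 180.0)
GGA_HUE_RANGE = (80.0, 180.0)

# IEC 61966-2-1 sRGB -> XYZ (D65). White point taken as the row sums so the
# sRGB white (1,1,1) maps exactly onto the achromatic origin.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_WHITE = _SRGB_TO_XYZ.sum(axis=1)  # (Xn, Yn, Zn)
_EPS_CBRT = (6.0 / 29.0) ** 3


@dataclass(frozen=True)
class RGBIndexSet:
    """Plot-level RGB statistics.

    ``hue`` is a circular mean in degrees; ``csi`` is a percentage.  ``hue``
    and ``csi`` are NaN when undefined (no saturated pixel / GA = 0).
    """

    intensity: float
    hue: float
    saturation: float
    lightness: float
    a_star: float
    b_star: float
    u_star: float
    v_star: float
    ga: float
    gga: float
    csi: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _validate_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected a trailing axis of 3 channels, got shape {rgb.shape}")
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(np.float64) / 255.0
    else:
        rgb = rgb.astype(np.float64)
    if rgb.size and (rgb.min() < -1e-12 or rgb.max() > 1.0 + 1e-12):
        raise ValueError("RGB channels must lie in [0, 1] (8-bit inputs are divided by 255)")
    return np.clip(rgb, 0.0, 1.0)


def srgb_to_hsi(rgb) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hexagonal hue (degrees), saturation and intensity of sRGB pixels.

    ``rgb`` is any array with a trailing axis of 3 channels in [0, 1] (or
    8-bit integers).  Intensity is the channel mean; saturation is the
    HSV chroma ratio (max-min)/max, defined as 0 on the grey axis where hue
    is returned as NaN.
    """
    rgb = _validate_rgb(rgb)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc

    intensity = rgb.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
        safe = np.where(delta > 0, delta, 1.0)
        hr = ((g - b) / safe) % 6.0
        hg = (b - r) / safe + 2.0
        hb = (r - g) / safe + 4.0
    hue = np.where(maxc == r, hr, np.where(maxc == g, hg, hb)) * 60.0
    hue = np.where(delta > 0, hue % 360.0, np.nan)
    return hue, saturation, intensity


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS_CBRT, np.cbrt(t), t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def srgb_to_lab_luv(rgb) -> tuple[np.ndarray, ...]:
    """(L*, a*, b*, u*, v*) for sRGB pixels under D65 / 2deg observer.

    Black maps to L* = 0 with all chromaticity coordinates 0 (the CIELuv
    u'v' chromaticity is undefined at zero luminance; the conventional
    limit u* = v* = 0 is used).
    """
    rgb = _validate_rgb(rgb)
    xyz = _srgb_to_linear(rgb) @ _SRGB_TO_XYZ.T
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    xn, yn, zn = _WHITE

    fx, fy, fz = _lab_f(x / xn), _lab_f(y / yn), _lab_f(z / zn)
    l_star = 116.0 * fy - 16.0
    a_star = 500.0 * (fx - fy)
    b_star = 200.0 * (fy - fz)

    denom = x + 15.0 * y + 3.0 * z
    denom_n = xn + 15.0 * yn + 3.0 * zn
    with np.errstate(invalid="ignore", divide="ignore"):
        u_prime = np.where(denom > 0, 4.0 * x / np.where(denom > 0, denom, 1.0), 4.0 * xn / denom_n)
        v_prime = np.where(denom > 0, 9.0 * y / np.where(denom > 0, denom, 1.0), 9.0 * yn / denom_n)
    u_star = 13.0 * l_star * (u_prime - 4.0 * xn / denom_n)
    v_star = 13.0 * l_star * (v_prime - 9.0 * yn / denom_n)
    return l_star, a_star, b_star, u_star, v_star


def csi(ga: float, gga: float) -> float:
    """Crop Senescence Index, CSI = (GA - GGA) / GA * 100 (percent).

    Returns NaN (missing) when GA = 0; raises if GGA exceeds GA or either
    falls outside [0, 1].
    """
    if not (0.0 <= gga <= 1.0 and 0.0 <= ga <= 1.0):
        raise ValueError(f"GA and GGA must be fractions in [0, 1], got ga={ga}, gga={gga}")
    if gga > ga + 1e-12:
        raise ValueError(f"GGA ({gga}) cannot exceed GA ({ga}); its hue range is a subset")
    if ga == 0.0:
        return float("nan")
    return (ga - min(gga, ga)) / ga * 100.0


def compute_rgb_indexes(image, intensity_mode: str = "mean") -> RGBIndexSet:
    """Compute the full RGB index set for one plot image.

    Parameters
    ----------
    image : array, shape (rows, cols, 3)
        8-bit or [0, 1]-float sRGB plot image.
    intensity_mode : {"mean", "value"}
        "mean" reports intensity as mean(R, G, B) per pixel (default);
        "value" reports the HSB brightness max(R, G, B) instead.

    Intensity, saturation, L*, a*, b*, u*, v* are arithmetic means over all
    pixels; hue is the circular mean over chromatic pixels; GA and GGA are
    fractions of *all* pixels whose (defined) hue falls in [60, 180) and
    [80, 180) degrees respectively.
    """
    if intensity_mode not in ("mean", "value"):
        raise ValueError(f"intensity_mode must be 'mean' or 'value', got {intensity_mode!r}")
    rgb = _validate_rgb(image)
    if rgb.ndim != 3 or rgb.shape[0] == 0 or rgb.shape[1] == 0:
        raise ValueError(f"expected a non-empty (rows, cols, 3) image, got shape {np.asarray(image).shape}")

    hue, sat, inten = srgb_to_hsi(rgb)
    if intensity_mode == "value":
        inten = rgb.max(axis=-1)
    l_star, a_star, b_star, u_star, v_star = srgb_to_lab_luv(rgb)

    n = hue.size
    chromatic = ~np.isnan(hue)
    if chromatic.any():
        rad = np.deg2rad(hue[chromatic])
        mean_hue = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
    else:
        mean_hue = float("nan")

    h = hue[chromatic]
    ga = float(np.count_nonzero((h >= GA_HUE_RANGE[0]) & (h < GA_HUE_RANGE[1]))) / n
    gga = float(np.count_nonzero((h >= GGA_HUE_RANGE[0]) & (h < GGA_HUE_RANGE[1]))) / n

    return RGBIndexSet(
        intensity=float(inten.mean()),
        hue=float(mean_hue),
        saturation=float(sat.mean()),
        lightness=float(l_star.mean()),
        a_star=float(a_star.mean()),
        b_star=float(b_star.mean()),
        u_star=float(u_star.mean()),
        v_star=float(v_star.mean()),
        ga=ga,
        gga=gga,
        csi=csi(ga, gga),
    )


def average_index_sets(sets: Sequence[RGBIndexSet] | Iterable[RGBIndexSet]) -> RGBIndexSet:
    """Arithmetic per-index average of several images of the same plot.

    Ground sampling protocols take several photographs per plot; indexes are
    computed per image and then averaged.  Note CSI is averaged across
    images, not recomputed from the averaged GA/GGA: CSI(mean) differs from
    mean(CSI) and the per-image convention is the one used here.  NaN values
    (undefined hue or CSI) are ignored per index; an all-NaN index stays NaN.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("cannot average an empty collection of index sets")
    fields = sets[0].as_dict().keys()
    out = {}
    for f in fields:
        vals = np.array([getattr(s, f) for s in sets], dtype=float)
        good = ~np.isnan(vals)
        out[f] = float(vals[good].mean()) if good.any() else float("nan")
    return RGBIndexSet(**out)
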