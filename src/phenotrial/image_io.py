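"""Reading, writing and cropping of the pipeline's image and table formats.

Conventions: all pixel coordinates are 0-based, row-major, origin top-left.
Regions of interest (ROIs) are half-open rectangles ``(row0, col0, row1,
col1)``: rows ``row0:row1`` and columns ``col0:col1``.

Formats: RGB plot images as PNG or JPEG (8-bit); multispectral cubes as
multi-page TIFF, one page per band in ascending wavelength order, 32-bit
float reflectance; thermal rasters as 32-bit float TIFF in degrees Celsius;
plot maps and trait tables as CSV with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PlotRecord",
    "MultispectralCube",
    "read_plot_map",
    "write_plot_map",
    "crop_roi",
    "read_ms_cube",
    "write_ms_cube",
    "read_rgb",
    "write_rgb",
    "read_thermal",
    "write_thermal",
]

#: columns a plot map must carry; ROI and agronomy columns are optional
PLOT_MAP_REQUIRED = ("plot_id", "tillage", "density", "hybrid", "rep")
ROI_COLUMNS = ("roi_row0", "roi_col0", "roi_row1", "roi_col1")

# reflectance slightly above 1 is tolerated (calibration overshoot); beyond
# this the cube is considered invalid
REFLECTANCE_MAX = 1.2


@dataclass(frozen=True)
class PlotRecord:
    """One plot's identity, treatment factors, ROI and agronomy."""

    plot_id: str
    tillage: str
    density: str
    hybrid: str
    rep: int
    roi: tuple[int, int, int, int] | None = None
    grain_yield: float | None = None
    biomass: float | None = None

    @property
    def harvest_index(self) -> float | None:
        """Grain yield as a fraction of total above-ground biomass."""
        if self.grain_yield is None or self.biomass is None or not self.biomass > 0:
            return None
        return self.grain_yield / self.biomass


def _validate_roi(roi: Sequence[int], shape: tuple[int, int] | None = None) -> tuple[int, int, int, int]:
    r0, c0, r1, c1 = (int(v) for v in roi)
    if not (r0 < r1 and c0 < c1):
        raise ValueError(f"ROI {tuple(roi)} is empty or inverted (need row0 < row1 and col0 < col1)")
    if r0 < 0 or c0 < 0:
        raise ValueError(f"ROI {tuple(roi)} has negative origin")
    if shape is not None and (r1 > shape[0] or c1 > shape[1]):
        raise ValueError(f"ROI {tuple(roi)} exceeds image bounds {shape}")
    return r0, c0, r1, c1


@dataclass(frozen=True)
class MultispectralCube:
    """A stack of 2-D reflectance rasters with their band centres (nm)."""

    bands: np.ndarray  # (n_bands, rows, cols) float
    band_centres: tuple[int, ...]

    def __post_init__(self):
        bands = np.asarray(self.bands, dtype=np.float32)
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "band_centres", tuple(int(w) for w in self.band_centres))
        if bands.ndim != 3:
            raise ValueError(f"cube must be (n_bands, rows, cols), got shape {bands.shape}")
        if bands.shape[0] != len(self.band_centres):
            raise ValueError(
                f"{bands.shape[0]} rasters but {len(self.band_centres)} band centres"
            )
        if list(self.band_centres) != sorted(set(self.band_centres)):
            raise ValueError(f"band centres must be strictly increasing, got {self.band_centres}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def band(self, centre: int) -> np.ndarray:
        """The 2-D raster for one band centre (nm)."""
        try:
            i = self.band_centres.index(int(centre))
        except ValueError:
            raise KeyError(f"no {centre} nm band; cube carries {self.band_centres}") from None
        return self.bands[i]

    def validate_reflectance(self) -> None:
        """Raise if any value falls outside [0, 1.2], citing band and count."""
        for w, raster in zip(self.band_centres, self.bands):
            bad = int(np.count_nonzero((raster < 0) | (raster > REFLECTANCE_MAX)))
            if bad:
                raise ValueError(
                    f"band {w} nm: {bad} pixel(s) outside the reflectance range [0, {REFLECTANCE_MAX}]"
                )


def read_plot_map(path) -> pd.DataFrame:
    """Read and validate a plot-map CSV.

    Requires columns plot_id, tillage, density, hybrid, rep; accepts
    optional ROI columns (roi_row0..roi_col1, half-open) and any agronomic
    or trait columns.  Rejects duplicate plot ids and malformed ROIs.
    """
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in PLOT_MAP_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"plot map {path} is missing required column(s): {missing}")
    dup = df["plot_id"][df["plot_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate plot_id in {path}: {sorted(dup.unique())}")
    if all(c in df.columns for c in ROI_COLUMNS):
        for _, row in df.iterrows():
            try:
                _validate_roi([row[c] for c in ROI_COLUMNS])
            except ValueError as e:
                raise ValueError(f"plot {row['plot_id']}: {e}") from None
    if {"grain_yield", "biomass"} <= set(df.columns) and "harvest_index" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["harvest_index"] = df["grain_yield"] / df["biomass"]
    return df


def write_plot_map(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def iter_records(df: pd.DataFrame):
    """Yield PlotRecord objects from a validated plot-map frame."""
    has_roi = all(c in df.columns for c in ROI_COLUMNS)
    for _, row in df.iterrows():
        yield PlotRecord(
            plot_id=str(row["plot_id"]),
            tillage=str(row["tillage"]),
            density=str(row["density"]),
            hybrid=str(row["hybrid"]),
            rep=int(row["rep"]),
            roi=tuple(int(row[c]) for c in ROI_COLUMNS) if has_roi else None,
            grain_yield=float(row["grain_yield"]) if "grain_yield" in df.columns else None,
            biomass=float(row["biomass"]) if "biomass" in df.columns else None,
        )


def crop_roi(image, roi: Sequence[int]):
    """Crop a half-open ROI from a 2-D raster, (rows, cols, ch) image or cube.

    Cropping a MultispectralCube crops every band identically and returns a
    new cube.  Raises on empty or out-of-bounds ROIs.
    """
    if isinstance(image, MultispectralCube):
        r0, c0, r1, c1 = _validate_roi(roi, image.shape)
        return MultispectralCube(image.bands[:, r0:r1, c0:c1], image.band_centres)
    arr = np.asarray(image)
    if arr.ndim < 2:
        raise ValueError(f"cannot crop an array of shape {arr.shape}")
    r0, c0, r1, c1 = _validate_roi(roi, arr.shape[:2])
    return arr[r0:r1, c0:c1]


def read_ms_cube(path, band_centres: Sequence[int], validate: bool = True) -> MultispectralCube:
    """Read a multi-page TIFF reflectance cube.

    Pages are mapped to ``band_centres`` in ascending wavelength order; the
    page count must match the band list and (when ``validate``) reflectance
    must lie within [0, 1.2].
    """
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(band_centres):
        raise ValueError(
            f"{path}: {pages.shape[0]} TIFF page(s) but {len(band_centres)} band centres"
        )
    cube = MultispectralCube(pages.astype(np.float32), tuple(band_centres))
    if validate:
        cube.validate_reflectance()
    return cube


def write_ms_cube(cube: MultispectralCube, path) -> None:
    """Write a cube as multi-page 32-bit float TIFF, ascending wavelength."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, cube.bands.astype(np.float32))


def read_rgb(path) -> np.ndarray:
    """Read an 8-bit RGB plot image (PNG or JPEG)."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel RGB image, got shape {img.shape}")
    return img


def write_rgb(image: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_thermal(path) -> np.ndarray:
    """Read a 32-bit float thermal raster (degrees Celsius)."""
    return tifffile.imread(path).astype(np.float32)


def write_thermal(raster: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(raster, dtype=np.float32))
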