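"""NDVI computation and raster-polygon/point aggregation.

NDVI = (NIR_780 − RED_660) / (NIR_780 + RED_660), per pixel.  Aggregation
uses the pixel-*center* containment rule throughout: a pixel belongs to a
polygon (or a point buffer) iff its center falls inside.  This is the
standard, tiling-invariant convention; edge pixels are not area-weighted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .paddocks import PaddockMap
from .raster import Raster

RED = "red_660"
NIR = "nir_780"


def compute_ndvi(scene: Raster, red_band: str = RED, nir_band: str = NIR) -> Raster:
    """Per-pixel NDVI raster from a two-band reflectance scene.

    Pixels where NIR+RED = 0 or either band is nodata are masked (NaN →
    nodata on write).  Values are mathematically confined to [−1, 1] for
    non-negative reflectances; soil/senescent pixels are *not* thresholded
    here.
    """
    scene.require_projected()
    red = scene.band(red_band)
    nir = scene.band(nir_band)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    out = Raster(
        data=ndvi[None],
        transform=scene.transform,
        crs=scene.crs,
        band_names=("ndvi",),
        meta={"source": scene.meta.get("scene_seed", None)},
    )
    return out


def _center_containment(raster: Raster, geometry) -> np.ndarray:
    """Boolean grid: pixel centers inside the geometry (bounding-box pruned)."""
    rows, cols = raster.shape
    t = raster.transform
    minx, miny, maxx, maxy = geometry.bounds
    r0, c0 = t.world_to_rowcol(minx, maxy)
    r1, c1 = t.world_to_rowcol(maxx, miny)
    r0, r1 = max(0, int(np.floor(r0)) - 1), min(rows, int(np.ceil(r1)) + 1)
    c0, c1 = max(0, int(np.floor(c0)) - 1), min(cols, int(np.ceil(c1)) + 1)
    inside = np.zeros((rows, cols), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return inside
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = t.pixel_center(rr, cc)
    g = prep(geometry)
    flat = np.fromiter(
        (g.contains(Point(xi, yi)) for xi, yi in zip(x.ravel(), y.ravel())),
        dtype=bool,
        count=x.size,
    )
    inside[r0:r1, c0:c1] = flat.reshape(x.shape)
    return inside


def zonal_mean(
    raster: Raster,
    polygons: PaddockMap,
    exclusion_mask: np.ndarray | None = None,
    band: int = 0,
) -> pd.DataFrame:
    """Mean raster value per polygon (pixel-center rule) with pixel counts.

    ``exclusion_mask`` (same grid, True = exclude) removes pixels such as
    previously harvested quadrat areas.  Polygons with zero valid pixels
    yield NaN with count 0, never an error.
    """
    if raster.crs != polygons.crs:
        raise ValueError(f"CRS mismatch: raster {raster.crs!r} vs polygons {polygons.crs!r}")
    grid = raster.data[band]
    invalid = raster.mask(band)
    if exclusion_mask is not None:
        invalid = invalid | np.asarray(exclusion_mask, dtype=bool)
    rows = []
    for p in polygons:
        inside = _center_containment(raster, p.geometry) & ~invalid
        n = int(inside.sum())
        rows.append(
            {
                "paddock_id": p.paddock_id,
                "species": p.species,
                "mean": float(grid[inside].mean()) if n else np.nan,
                "pixel_count": n,
                "area_ha": p.area_ha,
            }
        )
    return pd.DataFrame(rows)


def buffer_extract(
    raster: Raster, points: pd.DataFrame, diameter: float = 1.0, band: int = 0
) -> pd.DataFrame:
    """Mean of unmasked pixels whose centers lie within diameter/2 of each point.

    ``points`` needs columns ``x, y`` (raster CRS).  Points outside the
    raster extent, or with no valid pixel in the buffer, give NaN with a
    warning, not an error.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    t = raster.transform
    grid = raster.data[band]
    invalid = raster.mask(band)
    rows_n, cols_n = raster.shape
    radius = diameter / 2.0
    out = points.copy()
    means, counts = [], []
    half_r = int(np.ceil(radius / t.dy)) + 1
    half_c = int(np.ceil(radius / t.dx)) + 1
    for x, y in zip(points["x"].to_numpy(float), points["y"].to_numpy(float)):
        row_f, col_f = t.world_to_rowcol(x, y)
        if not (0 <= row_f <= rows_n and 0 <= col_f <= cols_n):
            warnings.warn(f"point ({x:.1f}, {y:.1f}) outside raster extent", stacklevel=2)
            means.append(np.nan)
            counts.append(0)
            continue
        r0, r1 = max(0, int(row_f) - half_r), min(rows_n, int(row_f) + half_r + 1)
        c0, c1 = max(0, int(col_f) - half_c), min(cols_n, int(col_f) + half_c + 1)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        px, py = t.pixel_center(rr, cc)
        sel = ((px - x) ** 2 + (py - y) ** 2 <= radius**2) & ~invalid[r0:r1, c0:c1]
        n = int(sel.sum())
        means.append(float(grid[r0:r1, c0:c1][sel].mean()) if n else np.nan)
        counts.append(n)
    out["buffer_mean"] = means
    out["buffer_count"] = counts
    return out
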