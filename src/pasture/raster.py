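"""Lightweight georeferenced raster container with GeoTIFF-style I/O.

A :class:`Raster` is a numpy array (``(bands, rows, cols)``) plus an affine
georeference, a CRS label and a nodata value.  All geometry in this package
lives in a projected CRS with metre units (a synthesized local system for
synthetic scenes), so pixel sizes and buffer distances are exact distances.

Files are written as TIFFs carrying the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON ImageDescription
with the CRS label and band names, and round-trip bit-exactly through
:func:`write_geotiff` / :func:`read_geotiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: CRS label used for synthesized local metric (transverse-Mercator-like) grids.
LOCAL_METRIC = "LOCAL_METRIC"

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Affine:
    """North-up affine georeference: world = origin + pixel * size.

    ``x0, y0`` is the world coordinate of the *outer corner* of pixel (0, 0);
    ``y`` decreases with increasing row (standard raster orientation).
    """

    x0: float
    y0: float
    dx: float
    dy: float  # positive pixel height; rows go downward in y

    def pixel_center(self, row, col):
        """World coordinates of pixel center(s)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def world_to_rowcol(self, x, y):
        """Fractional (row, col) for world coordinates."""
        col = (np.asarray(x) - self.x0) / self.dx
        row = (self.y0 - np.asarray(y)) / self.dy
        return row, col


@dataclass
class Raster:
    """Multiband raster with affine georeference and nodata mask."""

    data: np.ndarray  # (bands, rows, cols) float
    transform: Affine
    crs: str = LOCAL_METRIC
    nodata: float = DEFAULT_NODATA
    band_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_3d(np.asarray(self.data, dtype=float))
        if self.data.ndim == 3 and self.data.shape[0] > self.data.shape[-1] and not self.band_names:
            pass  # caller supplied (bands, rows, cols) already; nothing to infer
        if not self.band_names:
            self.band_names = tuple(f"band_{i + 1}" for i in range(self.data.shape[0]))
        if len(self.band_names) != self.data.shape[0]:
            raise ValueError("band_names length must match band count")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def pixel_area(self) -> float:
        return self.transform.dx * self.transform.dy

    def band(self, name: str) -> np.ndarray:
        """Return one band by name, with nodata as NaN."""
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(f"raster has no band named {name!r}; bands: {self.band_names}") from None
        out = self.data[i].copy()
        out[self.mask(i)] = np.nan
        return out

    def mask(self, band: int = 0) -> np.ndarray:
        """Boolean mask, True where the pixel is nodata/invalid."""
        b = self.data[band]
        return ~np.isfinite(b) | (b == self.nodata)

    def pixel_centers(self):
        """(X, Y) meshgrids of pixel-center world coordinates."""
        rows, cols = self.shape
        return self.transform.pixel_center(*np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"))

    def with_data(self, data: np.ndarray, band_names=None) -> "Raster":
        r = replace(self, data=np.atleast_3d(data))
        if band_names is not None:
            r.band_names = tuple(band_names)
        else:
            r.band_names = tuple(f"band_{i + 1}" for i in range(r.data.shape[0]))
        return r

    def require_projected(self):
        if self.crs.upper().startswith(("EPSG:4326", "GEOGRAPHIC", "WGS84")):
            raise ValueError(
                f"raster CRS {self.crs!r} is geographic; reproject to a metric projected CRS first"
            )


def write_geotiff(path, raster: Raster) -> None:
    """Write a raster as a TIFF with georeferencing tags (nodata honoured)."""
    t = raster.transform
    desc = json.dumps(
        {"crs": raster.crs, "bands": list(raster.band_names), "nodata": raster.nodata, **raster.meta}
    )
    data = raster.data.astype("float64")
    data = np.where(np.isfinite(data), data, raster.nodata)
    if data.shape[0] == 1:
        data = data[0]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.ndim == 3 else None,
        description=desc,
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0), True),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0), True),
            (_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata), True),
        ],
    )


def read_geotiff(path) -> Raster:
    """Read a TIFF written by :func:`write_geotiff` (or any north-up GeoTIFF)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie = page.tags.get(_TAG_MODEL_TIEPOINT)
        nod = page.tags.get(_TAG_GDAL_NODATA)
        desc = page.description
    if data.ndim == 2:
        data = data[None]
    if scale is None or tie is None:
        raise ValueError(f"{path}: missing georeferencing tags (ModelPixelScale/ModelTiepoint)")
    dx, dy = float(scale.value[0]), float(scale.value[1])
    x0, y0 = float(tie.value[3]), float(tie.value[4])
    crs, bands, meta = LOCAL_METRIC, None, {}
    nodata = float(nod.value) if nod is not None else DEFAULT_NODATA
    if desc:
        try:
            info = json.loads(desc)
            crs = info.pop("crs", crs)
            bands = info.pop("bands", None)
            nodata = float(info.pop("nodata", nodata))
            meta = info
        except (json.JSONDecodeError, TypeError):
            pass
    return Raster(
        data=data,
        transform=Affine(x0=x0, y0=y0, dx=dx, dy=dy),
        crs=crs,
        nodata=nodata,
        band_names=tuple(bands) if bands else (),
        meta=meta,
    )
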