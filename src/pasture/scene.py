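"""Synthetic pasture scenes with known ground truth.

Generates everything the downstream pipeline consumes — paddock polygons,
spatially autocorrelated biomass fields, the matching red/NIR reflectance
bands, line transects and grazing schedules — so the whole toolchain is
testable end-to-end without any field data.

The biomass field is lognormal with a Gaussian-filter spatial correlation
structure.  Reflectance is constructed by *inverting* the exponential
NDVI→biomass calibration: NDVI = ln(biomass/α)/β (optionally with
multiplicative lognormal noise on biomass), the NIR band is held at a fixed
canopy profile and the red band solved from the target NDVI.  A noiseless
scene therefore round-trips biomass → NDVI → biomass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box

from .paddocks import Paddock, PaddockMap
from .raster import LOCAL_METRIC, Affine, Raster

#: default exponential calibration placing biomass 226–4208 kg DM/ha on NDVI 0.23–0.78
DEFAULT_ALPHA = 66.5
DEFAULT_BETA = 5.32

#: fixed NIR canopy reflectance profile used when solving the red band
NIR_LEVEL = 0.45


@dataclass(frozen=True)
class SceneSpec:
    """Layout and statistical description of a synthetic grazing platform.

    Defaults emulate the study platform: two blocks of eight 1-ha
    (200 m x 50 m) paddocks, biomass spanning roughly 250-4000 kg DM/ha.
    """

    n_paddocks: int = 16
    paddock_dims: tuple[float, float] = (200.0, 50.0)  # (length, width) m
    pixel_size: float = 2.0  # m
    biomass_field: tuple[float, float, float] = (1800.0, 30.0, 0.45)  # mean kg/ha, corr len m, CV
    true_calibration: tuple[float, float] = (DEFAULT_ALPHA, DEFAULT_BETA)
    noise_cv: float = 0.0
    biomass_clip: tuple[float, float] = (250.0, 4000.0)
    species_pattern: tuple[str, ...] = ("fescue", "ryegrass")
    seed: int = 0

    def __post_init__(self):
        if self.n_paddocks < 1:
            raise ValueError("n_paddocks must be >= 1")
        length, width = self.paddock_dims
        if length <= 0 or width <= 0 or self.pixel_size <= 0:
            raise ValueError("paddock dimensions and pixel size must be positive")
        mean, corr, cv = self.biomass_field
        if mean <= 0 or cv < 0:
            raise ValueError("biomass mean must be positive and CV non-negative")
        if corr < self.pixel_size:
            raise ValueError("correlation length must be >= pixel size")
        alpha, _ = self.true_calibration
        if alpha <= 0:
            raise ValueError("calibration alpha must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _layout(spec: SceneSpec):
    """Paddock grid: two rows (blocks) when the count is even, else one."""
    n = spec.n_paddocks
    n_rows = 2 if n % 2 == 0 and n > 1 else 1
    n_cols = n // n_rows
    length, width = spec.paddock_dims
    return n_rows, n_cols, length, width


def generate_scene(spec: SceneSpec):
    """Build (reflectance scene, paddock map, true biomass raster).

    Deterministic for a given spec (seed included).  The reflectance scene
    has bands ``red_660`` and ``nir_780``; NDVI computed from them equals
    ln(noisy_biomass/alpha)/beta per pixel.
    """
    n_rows, n_cols, length, width = _layout(spec)
    px = spec.pixel_size
    cols = int(round(n_cols * length / px))
    rows = int(round(n_rows * width / px))
    transform = Affine(x0=0.0, y0=n_rows * width, dx=px, dy=px)
    rng = np.random.default_rng(spec.seed)

    mean, corr_len, cv = spec.biomass_field
    z = rng.standard_normal((rows, cols))
    z = gaussian_filter(z, sigma=corr_len / px, mode="reflect")
    sd = z.std()
    z = z / sd if sd > 0 else z
    sigma = np.sqrt(np.log(1.0 + cv**2))
    biomass = mean * np.exp(sigma * z - sigma**2 / 2.0)
    biomass = np.clip(biomass, *spec.biomass_clip)

    alpha, beta = spec.true_calibration
    observed = biomass
    if spec.noise_cv > 0:
        s = np.sqrt(np.log(1.0 + spec.noise_cv**2))
        observed = biomass * np.exp(s * rng.standard_normal(biomass.shape) - s**2 / 2.0)
    ndvi = np.log(observed / alpha) / beta
    ndvi = np.clip(ndvi, -0.999, 0.999)

    nir = np.full_like(ndvi, NIR_LEVEL)
    red = np.clip(nir * (1.0 - ndvi) / (1.0 + ndvi), 0.0, 1.0)

    scene = Raster(
        data=np.stack([red, nir]),
        transform=transform,
        crs=LOCAL_METRIC,
        band_names=("red_660", "nir_780"),
        meta={"scene_seed": spec.seed, "true_alpha": alpha, "true_beta": beta},
    )
    truth = Raster(
        data=biomass[None],
        transform=transform,
        crs=LOCAL_METRIC,
        band_names=("biomass_kg_ha",),
    )

    paddocks = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            geom = box(c * length, (n_rows - 1 - r) * width, (c + 1) * length, (n_rows - r) * width)
            species = spec.species_pattern[r % len(spec.species_pattern)]
            paddocks.append(Paddock(paddock_id=f"P{k + 1:02d}", geometry=geom, species=species))
            k += 1
    pmap = PaddockMap(paddocks=paddocks, crs=LOCAL_METRIC)
    return scene, pmap, truth


def sample_transect(
    raster: Raster,
    paddock: Paddock,
    spacing: float = 2.7,
    seed: int = 0,
    band: int = 0,
) -> pd.DataFrame:
    """Sample raster values along a line transect inside a paddock.

    The transect runs along the paddock's long axis at a randomized lateral
    offset (emulating a towed-sensor track), with points every ``spacing``
    metres; ~74 points for a 200-m paddock at the sensor's 2.7-m footprint.
    Returns columns ``paddock_id, x, y, value`` plus a ``sparse`` attribute
    flag when fewer than 2 points fit.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    minx, miny, maxx, maxy = paddock.geometry.bounds
    t = raster.transform
    rminx, rmaxx = t.x0, t.x0 + raster.shape[1] * t.dx
    rminy, rmaxy = t.y0 - raster.shape[0] * t.dy, t.y0
    if maxx < rminx or minx > rmaxx or maxy < rminy or miny > rmaxy:
        raise ValueError(f"paddock {paddock.paddock_id} lies outside the raster extent")

    rng = np.random.default_rng(seed)
    width = maxy - miny
    yline = miny + width * (0.5 + rng.uniform(-0.25, 0.25))
    line = LineString([(minx, yline), (maxx, yline)]).intersection(paddock.geometry)
    if line.is_empty:
        raise ValueError(f"transect line misses paddock {paddock.paddock_id}")
    if line.geom_type == "MultiLineString":
        line = max(line.geoms, key=lambda g: g.length)
    margin = min(1.0, line.length / 4)
    usable = line.length - 2 * margin
    n_pts = max(1, int(np.floor(usable / spacing)) + 1)
    dists = margin + np.arange(n_pts) * spacing

    xs, ys, vals = [], [], []
    grid = raster.data[band]
    maskgrid = raster.mask(band)
    for d in dists:
        p = line.interpolate(float(d))
        row, col = t.world_to_rowcol(p.x, p.y)
        r, c = int(row), int(col)
        if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1] and not maskgrid[r, c]:
            v = grid[r, c]
        else:
            v = np.nan
        xs.append(p.x)
        ys.append(p.y)
        vals.append(v)
    out = pd.DataFrame({"paddock_id": paddock.paddock_id, "x": xs, "y": ys, "value": vals})
    out.attrs["sparse"] = n_pts < 2 or spacing > line.length
    return out


def generate_grazing_schedule(
    pmap: PaddockMap, rotation_length: int = 16, seed: int = 0, as_of: str = "2016-07-18"
) -> pd.DataFrame:
    """Days-of-regrowth per paddock from a staggered rotation (one entry/day)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pmap))
    as_of_ts = pd.Timestamp(as_of)
    rows = []
    for slot, p in zip(order, pmap):
        days = int(slot) % rotation_length + 1
        rows.append(
            {
                "paddock_id": p.paddock_id,
                "species": p.species,
                "last_grazing_date": (as_of_ts - pd.Timedelta(days=days)).strftime("%Y-%m-%d"),
                "days_of_regrowth": days,
            }
        )
    return pd.DataFrame(rows)
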