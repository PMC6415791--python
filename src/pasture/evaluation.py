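"""Agreement statistics and method-comparison protocols.

Implements the full model-evaluation toolkit: deviations (estimate −
reference), RMSE, relative prediction error (RE = RMSE / reference mean ×
100), mean bias, Pearson r, R², the regression accuracy test (intercept =
0, slope = 1), Lin's concordance correlation coefficient

    CCC = 2·cov(x, y) / (var(x) + var(y) + (x̄ − ȳ)²)

with population (1/n) moments, and its bias-correction factor Cb = CCC/r.
Also the three-way comparison of a remote estimate against the mean of two
ground-truth instruments, and the transect pipeline that intersects
NDVI-derived biomass with height-calibrated transect points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ExpCalibration, LinearHeightCalibration, apply_height_calibration, predict_biomass
from .ndvi import buffer_extract
from .paddocks import PaddockMap
from .raster import Raster


@dataclass
class PairedSeries:
    """Aligned (reference, estimate) vectors; missing pairs dropped listwise."""

    reference: np.ndarray
    estimate: np.ndarray
    ids: list | None = None
    n_dropped: int = 0

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        est = np.asarray(self.estimate, dtype=float)
        if ref.shape != est.shape or ref.ndim != 1:
            raise ValueError("reference and estimate must be equal-length 1-D vectors")
        ok = np.isfinite(ref) & np.isfinite(est)
        self.n_dropped = int((~ok).sum())
        self.reference = ref[ok]
        self.estimate = est[ok]
        if self.ids is not None:
            self.ids = [i for i, keep in zip(self.ids, ok) if keep]
        if len(self.reference) < 2:
            raise ValueError("need at least 2 complete pairs")

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass
class EvalReport:
    bias: float
    rmse: float
    re_percent: float
    r: float
    r2: float
    ccc: float
    cb: float
    intercept: float
    slope: float
    p_intercept_zero: float
    p_slope_one: float
    n: int
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def lin_ccc(reference, estimate) -> tuple[float, float]:
    """Lin's CCC and bias-correction factor Cb, population moments.

    Returns (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(estimate, dtype=float)
    vx, vy = x.var(), y.var()  # population (1/n)
    if vx == 0 or vy == 0:
        return float("nan"), float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    ccc = 2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2)
    r = cov / np.sqrt(vx * vy)
    cb = ccc / r if r != 0 else float("nan")
    return float(ccc), float(cb)


def agreement(series: PairedSeries) -> EvalReport:
    """Full agreement report between an estimate and its reference.

    The accuracy regression is reference ~ estimate (OLS, sample moments),
    with two-sided t-tests of intercept = 0 and slope = 1.
    """
    ref, est = series.reference, series.estimate
    n = series.n
    if n < 3:
        raise ValueError("need at least 3 pairs for the agreement report")
    if ref.mean() == 0:
        raise ValueError("reference mean is zero; RE undefined")
    dev = est - ref
    bias = float(dev.mean())
    rmse = float(np.sqrt(np.mean(dev**2)))
    re = rmse / ref.mean() * 100.0

    if est.var() == 0 or ref.var() == 0:
        r = r2 = ccc = cb = slope = intercept = float("nan")
        p_int = p_slope = float("nan")
    else:
        lr = stats.linregress(est, ref)
        slope, intercept = float(lr.slope), float(lr.intercept)
        r = float(lr.rvalue)
        r2 = r * r
        # standard errors from the OLS machinery (sample moments)
        resid = ref - (intercept + slope * est)
        dof = n - 2
        s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        sxx = float(((est - est.mean()) ** 2).sum())
        se_slope = np.sqrt(s2 / sxx)
        se_int = np.sqrt(s2 * (1.0 / n + est.mean() ** 2 / sxx))
        with np.errstate(divide="ignore", invalid="ignore"):  # perfect fits have zero SEs
            p_slope = (
                float(2 * stats.t.sf(abs((slope - 1.0) / se_slope), dof)) if dof > 0 else float("nan")
            )
            p_int = float(2 * stats.t.sf(abs(intercept / se_int), dof)) if dof > 0 else float("nan")
        ccc, cb = lin_ccc(ref, est)
    return EvalReport(
        bias=bias,
        rmse=rmse,
        re_percent=float(re),
        r=r,
        r2=r2,
        ccc=ccc,
        cb=cb,
        intercept=intercept,
        slope=slope,
        p_intercept_zero=p_int,
        p_slope_one=p_slope,
        n=n,
        n_dropped=series.n_dropped,
    )


def compare_methods(
    uav: pd.Series | np.ndarray,
    cdax: pd.Series | np.ndarray,
    ruler: pd.Series | np.ndarray,
    ids=None,
    band_kg: float = 500.0,
) -> dict:
    """Compare a remote estimate against the mean of two control methods.

    Deviation_i = UAV_i − (CDax_i + Ruler_i)/2, RMSE over those deviations,
    paired two-sided t-tests of the remote method against each control, and
    the fraction of observations with |deviation| ≤ ``band_kg``.
    """
    uav, cdax, ruler = (np.asarray(v, dtype=float) for v in (uav, cdax, ruler))
    if not (len(uav) == len(cdax) == len(ruler)):
        raise ValueError("method vectors must be aligned (equal length)")
    if ids is not None:
        ids = list(ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"misaligned ids (duplicates): {dupes}")
    control = (cdax + ruler) / 2.0
    dev = uav - control
    rmse = float(np.sqrt(np.mean(dev**2)))
    t_cdax = stats.ttest_rel(uav, cdax)
    t_ruler = stats.ttest_rel(uav, ruler)
    t_control = stats.ttest_rel(uav, control)
    return {
        "n": len(uav),
        "bias": float(dev.mean()),
        "rmse": rmse,
        "within_band_fraction": float(np.mean(np.abs(dev) <= band_kg)),
        "band_kg": band_kg,
        "t_vs_cdax": {"t": float(t_cdax.statistic), "p": float(t_cdax.pvalue)},
        "t_vs_ruler": {"t": float(t_ruler.statistic), "p": float(t_ruler.pvalue)},
        "t_vs_control_mean": {"t": float(t_control.statistic), "p": float(t_control.pvalue)},
        "deviations": dev,
    }


def transect_compare(
    ndvi_raster: Raster,
    cal: ExpCalibration,
    transects: pd.DataFrame,
    height_cals: dict[str, LinearHeightCalibration],
    paddocks: PaddockMap,
    height_unit: str,
    buffer_diameter: float = 1.0,
) -> pd.DataFrame:
    """Paddock-level pairing of NDVI-derived and height-derived biomass.

    For each transect point (columns ``paddock_id, x, y, height``): extract
    the mean NDVI in a buffer around the point, convert to biomass with the
    exponential calibration, and average per paddock; pair with the
    height-calibrated transect mean (per-species calibration).  Paddocks
    whose points are all masked are skipped with a warning column.
    """
    required = {"paddock_id", "x", "y", "height"}
    if not required.issubset(transects.columns):
        raise ValueError(f"transect table needs columns {sorted(required)}")
    rows = []
    for p in paddocks:
        pts = transects[transects["paddock_id"] == p.paddock_id]
        if pts.empty:
            continue
        extracted = buffer_extract(ndvi_raster, pts, diameter=buffer_diameter)
        valid = extracted["buffer_mean"].notna()
        if not valid.any():
            continue  # all points masked: skip this paddock
        ndvi_mean = extracted.loc[valid, "buffer_mean"].to_numpy()
        biomass_uav, _ = predict_biomass(cal, ndvi_mean)
        hc = height_cals.get(p.species) or height_cals.get("any")
        if hc is None:
            raise ValueError(f"no height calibration for species {p.species!r}")
        biomass_h, _ = apply_height_calibration(hc, pts["height"].to_numpy(), height_unit)
        rows.append(
            {
                "paddock_id": p.paddock_id,
                "species": p.species,
                "uav_biomass": float(np.mean(biomass_uav)),
                "transect_biomass": float(np.mean(biomass_h)),
                "n_points": int(valid.sum()),
                "n_masked": int((~valid).sum()),
            }
        )
    return pd.DataFrame(rows)
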