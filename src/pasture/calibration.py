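"""Biomass predictors: exponential NDVI calibration and linear height rules.

The central relation is the exponential calibration

    biomass_i = alpha * exp(beta * NDVI_i)        [kg DM ha^-1]

fitted by nonlinear least squares on the original biomass scale,
initialized from the log-linear regression ln(biomass) = ln(alpha) +
beta*NDVI.  Tow-behind pasture-meter and sward-ruler height readings are
converted with linear calibrations carrying explicit height units (the two
instruments report mm and cm respectively — silent unit coercion is a
classic field-data bug and is rejected here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

#: NDVI above which the index saturates and predictions are flagged
SATURATION_NDVI = 0.8


@dataclass
class ExpCalibration:
    """Fitted exponential NDVI→biomass calibration with diagnostics."""

    alpha: float
    beta: float
    r2: float
    n: int
    residual_sd: float
    ndvi_range: tuple[float, float]
    sse: float = 0.0
    uninformative: bool = False

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def predict(self, ndvi, saturation_threshold: float = SATURATION_NDVI):
        return predict_biomass(self, ndvi, saturation_threshold)

    def to_json(self, path=None) -> str:
        doc = {
            "model": "biomass = alpha * exp(beta * ndvi)",
            "alpha": self.alpha,
            "beta": self.beta,
            "r2": self.r2,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "ndvi_range": list(self.ndvi_range),
            "uninformative": self.uninformative,
        }
        s = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "ExpCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha=d["alpha"],
            beta=d["beta"],
            r2=d["r2"],
            n=d["n"],
            residual_sd=d["residual_sd"],
            ndvi_range=tuple(d["ndvi_range"]),
            uninformative=d.get("uninformative", False),
        )


@dataclass
class LinearHeightCalibration:
    """Linear sward height → biomass rule with an explicit height unit."""

    slope: float  # kg DM/ha per height unit
    intercept: float  # kg DM/ha
    height_unit: str  # "mm" | "cm"
    species: str = "any"

    def __post_init__(self):
        if self.height_unit not in ("mm", "cm"):
            raise ValueError(f"height_unit must be 'mm' or 'cm', got {self.height_unit!r}")


#: printed field calibrations: pasture-meter heights in mm, ruler heights in cm
CDAX_FESCUE = LinearHeightCalibration(slope=15.0, intercept=-150.0, height_unit="mm", species="fescue")
CDAX_RYEGRASS = LinearHeightCalibration(slope=17.0, intercept=-57.0, height_unit="mm", species="ryegrass")
RULER_BOTH = LinearHeightCalibration(slope=123.0, intercept=-515.0, height_unit="cm", species="any")


def _exp_model(ndvi, alpha, beta):
    return alpha * np.exp(beta * ndvi)


def _loglinear_init(ndvi, biomass):
    slope, intercept = stats.linregress(ndvi, np.log(biomass))[:2]
    return float(np.exp(intercept)), float(slope)


def fit_exponential(ndvi, biomass) -> ExpCalibration:
    """Fit biomass = alpha*exp(beta*NDVI) by NLS on the biomass scale.

    Initialized from the log-linear fit; reports R² on the original scale.
    Rejects degenerate NDVI (zero variance) and non-positive biomass.  A
    flat response (beta ≈ 0) yields alpha = geometric mean of biomass and
    is flagged uninformative.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    biomass = np.asarray(biomass, dtype=float)
    if ndvi.shape != biomass.shape or ndvi.ndim != 1:
        raise ValueError("ndvi and biomass must be equal-length 1-D vectors")
    if len(ndvi) < 4:
        raise ValueError("need at least 4 calibration points")
    if np.any(biomass <= 0):
        raise ValueError("biomass must be strictly positive")
    if np.any((ndvi <= -1) | (ndvi >= 1)):
        raise ValueError("NDVI must lie in (-1, 1)")
    if np.ptp(ndvi) == 0:
        raise ValueError("degenerate calibration data: NDVI has zero variance")

    a0, b0 = _loglinear_init(ndvi, biomass)
    try:
        popt, _ = optimize.curve_fit(_exp_model, ndvi, biomass, p0=[a0, b0], maxfev=20_000)
        alpha, beta = float(popt[0]), float(popt[1])
    except RuntimeError:
        alpha, beta = a0, b0

    pred = _exp_model(ndvi, alpha, beta)
    resid = biomass - pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((biomass - biomass.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    dof = max(1, len(ndvi) - 2)
    uninformative = abs(beta) * np.ptp(ndvi) < 1e-8
    if uninformative:
        alpha = float(np.exp(np.mean(np.log(biomass))))  # geometric mean
        beta = 0.0
    return ExpCalibration(
        alpha=alpha,
        beta=beta,
        r2=r2,
        n=len(ndvi),
        residual_sd=float(np.sqrt(sse / dof)),
        ndvi_range=(float(ndvi.min()), float(ndvi.max())),
        sse=sse,
        uninformative=uninformative,
    )


def predict_biomass(cal: ExpCalibration, ndvi, saturation_threshold: float = SATURATION_NDVI):
    """alpha*exp(beta*NDVI) with a saturation flag above the NDVI threshold.

    Returns ``(biomass, saturated)`` arrays (or scalars for scalar input).
    Predictions are flagged, never truncated.
    """
    arr = np.asarray(ndvi, dtype=float)
    pred = _exp_model(arr, cal.alpha, cal.beta)
    saturated = arr > saturation_threshold
    if np.isscalar(ndvi) or arr.ndim == 0:
        return float(pred), bool(saturated)
    return pred, saturated


def apply_height_calibration(cal: LinearHeightCalibration, height, height_unit: str):
    """Convert sward height to biomass; negative predictions floored at 0.

    The caller must declare the unit of ``height``; a mismatch with the
    calibration's unit is an error, never silently converted.
    Returns ``(biomass, floored_flag)``.
    """
    if height_unit != cal.height_unit:
        raise ValueError(
            f"height unit mismatch: data in {height_unit!r}, calibration expects {cal.height_unit!r}"
        )
    h = np.asarray(height, dtype=float)
    if np.any(h < 0):
        raise ValueError("height must be non-negative")
    raw = cal.slope * h + cal.intercept
    floored = raw < 0
    pred = np.where(floored, 0.0, raw)
    if np.isscalar(height) or h.ndim == 0:
        return float(pred), bool(floored)
    return pred, floored


def compare_species_fits(
    ndvi_a, biomass_a, ndvi_b, biomass_b, alpha_level: float = 0.05
) -> dict:
    """Extra-sum-of-squares F-test: pooled vs per-species exponential fits.

    Pooling is recommended when the fits do not differ (p > alpha_level),
    mirroring the common-calibration decision for the two pasture species.
    Returns F, df, p-value and the recommendation.
    """
    for v, name in ((ndvi_a, "a"), (ndvi_b, "b")):
        if len(np.asarray(v)) < 4:
            raise ValueError(f"group {name}: need at least 4 points")
    fit_a = fit_exponential(ndvi_a, biomass_a)
    fit_b = fit_exponential(ndvi_b, biomass_b)
    ndvi_p = np.concatenate([np.asarray(ndvi_a, float), np.asarray(ndvi_b, float)])
    bio_p = np.concatenate([np.asarray(biomass_a, float), np.asarray(biomass_b, float)])
    fit_p = fit_exponential(ndvi_p, bio_p)
    sse_sep = fit_a.sse + fit_b.sse
    n = len(ndvi_p)
    df_num, df_den = 2, n - 4
    if df_den <= 0:
        raise ValueError("insufficient combined sample size for the F-test")
    if sse_sep <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = max(0.0, (fit_p.sse - sse_sep) / df_num / (sse_sep / df_den))
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return {
        "F": float(f_stat),
        "df": (df_num, df_den),
        "p_value": p,
        "pool": p > alpha_level,
        "pooled_fit": fit_p,
        "fit_a": fit_a,
        "fit_b": fit_b,
    }


@dataclass
class LaiRelation:
    """Saturating NDVI(LAI) fit: ndvi = c - a*exp(-b*LAI)."""

    c: float
    a: float
    b: float
    r2: float
    n: int

    @property
    def soil_ndvi(self) -> float:
        """Fitted NDVI at LAI = 0 (the bare-soil intercept)."""
        return self.c - self.a

    def predict(self, lai):
        return self.c - self.a * np.exp(-self.b * np.asarray(lai, dtype=float))


def fit_lai_relation(ndvi, lai) -> LaiRelation:
    """Fit the saturating NDVI–LAI curve ndvi = c − a·exp(−b·LAI).

    Same exponential family as the biomass calibration, inverted
    orientation: NDVI rises from a soil-line intercept toward an asymptote
    c as leaf area accumulates (saturating near LAI ~ 3).
    """
    ndvi = np.asarray(ndvi, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if len(ndvi) < 4:
        raise ValueError("need at least 4 points")
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    if np.ptp(lai) == 0:
        raise ValueError("degenerate data: LAI has zero variance")
    c0 = float(ndvi.max()) + 0.05
    a0 = max(1e-3, c0 - float(ndvi.min()))
    b0 = 1.0
    popt, _ = optimize.curve_fit(
        lambda x, c, a, b: c - a * np.exp(-b * x), lai, ndvi, p0=[c0, a0, b0], maxfev=20_000
    )
    c, a, b = (float(v) for v in popt)
    pred = c - a * np.exp(-b * lai)
    sst = float(np.sum((ndvi - ndvi.mean()) ** 2))
    sse = float(np.sum((ndvi - pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return LaiRelation(c=c, a=a, b=b, r2=r2, n=len(ndvi))
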