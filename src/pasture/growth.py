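"""Daily pasture regrowth from radiation use efficiency x intercepted PAR.

This is a deliberately reduced crop-growth kernel: above-ground growth is

    dB/dt = RUE * (srad * par_fraction) * (1 - exp(-k_ext * LAI)) * f_temp * min(f_water, f_N)

in g DM m^-2 d^-1 (reported as kg DM ha^-1 d^-1), with LAI fed back from
the leaf-partitioned share of growth via specific leaf area, and
development clocked by thermal time above a base temperature.  Soil water
and nitrogen balances are *not* simulated; stress enters as exogenous
multipliers in [0, 1] supplied by the caller (1 = unstressed), keeping the
planner's contract — a daily growth rate — while staying fully
parameter-transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import RULER_BOTH, LinearHeightCalibration, apply_height_calibration
from .weather import WeatherSeries

G_PER_M2_TO_KG_PER_HA = 10.0


@dataclass(frozen=True)
class GrowthParameters:
    """Radiation-use-efficiency growth parameters for a C3 pasture sward."""

    rue: float = 0.9  # g above-ground DM per MJ intercepted PAR (0.8-1.2 typical; conservative end)
    k_ext: float = 0.6  # canopy light extinction coefficient
    par_fraction: float = 0.48  # PAR fraction of global solar radiation
    sla: float = 25.0  # m^2 leaf per kg DM
    leaf_partition: float = 0.6  # fraction of new growth allocated to leaf
    t_base: float = 4.0  # deg C, base temperature for C3 grasses
    t_opt: tuple[float, float] = (16.0, 25.0)  # deg C plateau of the temperature response

    def __post_init__(self):
        if self.rue <= 0:
            raise ValueError("rue must be positive")
        if not 0 < self.k_ext <= 1.2:
            raise ValueError("k_ext must be in (0, 1.2]")
        if not 0 < self.par_fraction <= 1:
            raise ValueError("par_fraction must be in (0, 1]")
        if self.sla <= 0 or not 0 <= self.leaf_partition <= 1:
            raise ValueError("invalid sla or leaf_partition")
        if self.t_base >= self.t_opt[0]:
            raise ValueError("t_base must be below the optimum range")


@dataclass(frozen=True)
class GrowthState:
    """Sward state: standing biomass, leaf area index, thermal-time clock."""

    date: pd.Timestamp | None
    biomass: float  # kg DM / ha
    lai: float
    thermal_time: float = 0.0  # cumulative deg C days

    def __post_init__(self):
        if self.biomass < 0 or self.lai < 0 or self.thermal_time < 0:
            raise ValueError("biomass, lai and thermal time must be non-negative")


def temperature_factor(tmean: float, params: GrowthParameters) -> float:
    """Piecewise-linear temperature response: 0 at t_base, 1 on the optimum plateau."""
    lo, hi = params.t_opt
    if tmean <= params.t_base:
        return 0.0
    if tmean < lo:
        return (tmean - params.t_base) / (lo - params.t_base)
    if tmean <= hi:
        return 1.0
    # linear decline above the plateau, reaching 0 at hi + (hi - lo)
    return max(0.0, 1.0 - (tmean - hi) / (hi - lo))


def step_day(
    state: GrowthState,
    weather_day,
    params: GrowthParameters,
    stress: dict | None = None,
) -> tuple[GrowthState, float]:
    """Advance one day; returns (new state, growth rate kg DM ha^-1 d^-1)."""
    stress = stress or {}
    f_water = stress.get("water", 1.0)
    f_n = stress.get("n", 1.0)
    if f_water < 0 or f_n < 0 or f_water > 1 or f_n > 1:
        raise ValueError("stress factors must lie in [0, 1]")
    tmean = (weather_day.tmin + weather_day.tmax) / 2.0
    f_temp = temperature_factor(tmean, params)
    ipar = weather_day.srad * params.par_fraction * (1.0 - np.exp(-params.k_ext * state.lai))
    growth_g_m2 = params.rue * ipar * f_temp * min(f_water, f_n)
    growth = growth_g_m2 * G_PER_M2_TO_KG_PER_HA
    dlai = growth * params.leaf_partition * params.sla / 1.0e4  # kg/ha * m2/kg -> m2/m2
    new = GrowthState(
        date=getattr(weather_day, "date", None),
        biomass=state.biomass + growth,
        lai=state.lai + dlai,
        thermal_time=state.thermal_time + max(0.0, tmean - params.t_base),
    )
    return new, growth


@dataclass
class GrowthTrajectory:
    states: list[GrowthState]
    rates: list[float] = field(default_factory=list)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates)) if self.rates else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "date": s.date,
                "biomass_kg_ha": s.biomass,
                "lai": s.lai,
                "thermal_time_cd": s.thermal_time,
                "growth_rate": r,
            }
            for s, r in zip(self.states[1:], self.rates)
        ]
        first = self.states[0]
        rows.insert(
            0,
            {
                "date": first.date,
                "biomass_kg_ha": first.biomass,
                "lai": first.lai,
                "thermal_time_cd": first.thermal_time,
                "growth_rate": np.nan,
            },
        )
        return pd.DataFrame(rows)


def simulate_regrowth(
    initial: GrowthState,
    weather: WeatherSeries,
    params: GrowthParameters,
    stress_series: list[dict] | dict | None = None,
    n_days: int | None = None,
) -> GrowthTrajectory:
    """Simulate daily regrowth over a horizon (default: the whole series).

    Mass balance holds exactly: final biomass = initial + sum of daily
    growth.  A constant stress dict applies every day; a list must cover
    the horizon.
    """
    horizon = len(weather) if n_days is None else n_days
    if horizon > len(weather):
        have = weather.frame["date"].iloc[-1].date()
        raise ValueError(f"weather gap: horizon {horizon} d but series ends {have}")
    if isinstance(stress_series, dict) or stress_series is None:
        stress_series = [stress_series or {}] * horizon
    if len(stress_series) < horizon:
        raise ValueError("stress series shorter than the horizon")
    states, rates = [initial], []
    for day, stress in zip(list(weather)[:horizon], stress_series):
        new, rate = step_day(states[-1], day, params, stress)
        states.append(new)
        rates.append(rate)
    return GrowthTrajectory(states=states, rates=rates)


def init_from_residual(
    params: GrowthParameters,
    residual_height_cm: float | None = None,
    residual_biomass: float | None = None,
    height_rule: LinearHeightCalibration = RULER_BOTH,
    date=None,
) -> GrowthState:
    """Initial state after grazing, from residual height *or* biomass.

    Height is converted with a linear height rule (ruler calibration by
    default, cm); initial LAI is the leaf fraction of biomass times SLA.
    """
    if (residual_height_cm is None) == (residual_biomass is None):
        raise ValueError("give exactly one of residual_height_cm or residual_biomass")
    if residual_height_cm is not None:
        if residual_height_cm <= 0:
            raise ValueError("residual height must be positive")
        residual_biomass, _ = apply_height_calibration(
            height_rule, residual_height_cm, height_rule.height_unit
        )
    if residual_biomass < 0:
        raise ValueError("residual biomass must be non-negative")
    lai = residual_biomass * params.leaf_partition * params.sla / 1.0e4
    return GrowthState(date=date, biomass=float(residual_biomass), lai=float(lai))


def replace_params(params: GrowthParameters, **kwargs) -> GrowthParameters:
    return replace(params, **kwargs)
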