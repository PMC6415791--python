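"""Grazing-rotation decisions from per-paddock biomass and a growth rate.

Three linear bookkeeping rules connect the remotely sensed standing biomass
(UAV_i, kg DM ha⁻¹) to rotation decisions via a daily growth rate G
(kg DM ha⁻¹ d⁻¹):

    post-grazing_i  = UAV_i − G × days_of_regrowth_i     (back-calculated residual)
    pre-grazing_i   = UAV_i + G × days_in_rotation       (forecast at entry)
    days-to-target_i = (Target − UAV_i) / G              (resting days needed)

Days are rounded *up*: reaching the target is a ≥ constraint.  The grazing
wedge ranks paddocks by standing biomass against the ideal line from the
pre-grazing to the post-grazing target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default management targets, kg DM/ha
PRE_GRAZING_TARGET = 2700.0
POST_GRAZING_TARGET = 1300.0
MIN_FARM_COVER = 1800.0

#: sentinel for unreachable targets (growth rate 0 below target)
UNREACHABLE = math.inf


@dataclass(frozen=True)
class PaddockState:
    """Per-paddock input to the planner."""

    paddock_id: str
    uav_biomass: float  # kg DM/ha standing biomass from the NDVI calibration
    days_of_regrowth: float  # days since last grazing at flight time
    species: str = "fescue"
    area_ha: float = 1.0

    def __post_init__(self):
        if self.uav_biomass < 0 or self.days_of_regrowth < 0:
            raise ValueError("biomass and days of regrowth must be non-negative")


def post_grazing(state: PaddockState, growth_rate: float) -> tuple[float, bool]:
    """Back-calculated residual biomass; floored at 0 with an inconsistency flag."""
    if growth_rate < 0:
        raise ValueError("growth rate must be non-negative")
    raw = state.uav_biomass - growth_rate * state.days_of_regrowth
    if raw < 0:
        return 0.0, True
    return raw, False


def pre_grazing(state: PaddockState, growth_rate: float, days_in_rotation: float) -> float:
    """Forecast biomass after ``days_in_rotation`` more days of growth."""
    if days_in_rotation < 0:
        raise ValueError("days_in_rotation must be non-negative")
    return state.uav_biomass + growth_rate * days_in_rotation


def days_to_target(state: PaddockState, growth_rate: float, target: float) -> tuple[float, bool]:
    """Whole days (ceiling) until the paddock reaches the biomass target.

    Returns ``(days, unreachable)``; 0 when already at/above target, an
    infinite sentinel with flag when growth is zero below target.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if state.uav_biomass >= target:
        return 0.0, False
    if growth_rate <= 0:
        return UNREACHABLE, True
    return float(math.ceil((target - state.uav_biomass) / growth_rate)), False


def build_wedge(
    states: list[PaddockState],
    growth_rate: float,
    target: float = PRE_GRAZING_TARGET,
    post_target: float = POST_GRAZING_TARGET,
    rotation_length: float | None = None,
) -> pd.DataFrame:
    """Grazing wedge: paddocks ranked by descending standing biomass.

    The ideal wedge line runs from ``target`` (rank 1) down to
    ``post_target`` (last rank).  Each paddock's scheduled slot in the
    rotation is its rank's share of ``rotation_length`` (default: one
    rank step per day); a paddock is flagged below-target when its
    forecast biomass at that slot falls short, and the plan reports the
    rotation extension (days) needed to lift every paddock to target.
    Ties rank in input order (stable sort) so plans are reproducible.
    """
    if not states:
        raise ValueError("need at least one paddock")
    n = len(states)
    rotation_length = float(rotation_length) if rotation_length is not None else float(n)
    order = sorted(range(n), key=lambda i: -states[i].uav_biomass)  # stable for ties
    rows = []
    for rank0, idx in enumerate(order):
        s = states[idx]
        frac = rank0 / (n - 1) if n > 1 else 0.0
        wedge_line = target - (target - post_target) * frac
        slot_days = frac * rotation_length
        forecast = pre_grazing(s, growth_rate, slot_days)
        dtt, unreachable = days_to_target(s, growth_rate, target)
        post, neg = post_grazing(s, growth_rate)
        deficit_days = max(0.0, dtt - slot_days) if not unreachable else UNREACHABLE
        rows.append(
            {
                "paddock_id": s.paddock_id,
                "species": s.species,
                "wedge_rank": rank0 + 1,
                "uav_biomass": s.uav_biomass,
                "wedge_line": wedge_line,
                "post_grazing": post,
                "negative_residual": neg,
                "scheduled_day": slot_days,
                "pre_grazing_forecast": forecast,
                "days_to_target": dtt,
                "target_unreachable": unreachable,
                "below_target": forecast < target,
                "deficit_days": deficit_days,
            }
        )
    plan = pd.DataFrame(rows)
    finite = plan.loc[plan["below_target"], "deficit_days"].replace(UNREACHABLE, np.nan).dropna()
    plan.attrs["recommended_extension_days"] = float(np.ceil(finite.max())) if len(finite) else 0.0
    plan.attrs["mean_cover"] = float(np.mean([s.uav_biomass for s in states]))
    plan.attrs["low_cover_warning"] = plan.attrs["mean_cover"] < MIN_FARM_COVER
    return plan


def states_from_frame(df: pd.DataFrame) -> list[PaddockState]:
    """PaddockState list from a table with columns paddock_id, uav_biomass, days_of_regrowth[, species, area_ha]."""
    return [
        PaddockState(
            paddock_id=str(r["paddock_id"]),
            uav_biomass=float(r["uav_biomass"]),
            days_of_regrowth=float(r["days_of_regrowth"]),
            species=str(r.get("species", "fescue")),
            area_ha=float(r.get("area_ha", 1.0)),
        )
        for _, r in df.iterrows()
    ]
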