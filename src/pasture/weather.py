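"""Daily weather series: container, validation, synthesis, CSV I/O.

A weather day carries minimum/maximum air temperature (°C), incoming solar
radiation (MJ m⁻² d⁻¹) and rainfall (mm) — the forcings the growth and
morphogenesis models need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["date", "tmin", "tmax", "srad", "rain"]

#: seasonal profile -> (mean tmean °C, diurnal range °C, mean srad MJ/m2/d, mean rain mm/d)
PROFILES = {
    "spring": (13.0, 9.0, 19.0, 2.8),
    "summer": (21.0, 10.0, 23.0, 2.5),
    "autumn": (10.0, 8.0, 11.0, 2.6),
    "constant": (20.0, 0.0, 20.0, 0.0),
}


@dataclass
class WeatherSeries:
    """Validated daily weather table with columns date,tmin,tmax,srad,rain."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"weather table missing columns: {missing}")
        df = df[COLUMNS].copy()
        df["date"] = pd.to_datetime(df["date"])
        if len(df) == 0:
            raise ValueError("weather series is empty")
        steps = df["date"].diff().dropna()
        if len(steps) and not (steps == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates must be strictly increasing with a daily step")
        if (df["tmax"] < df["tmin"]).any():
            raise ValueError("tmax < tmin in weather series")
        if (df["srad"] < 0).any() or (df["rain"] < 0).any():
            raise ValueError("negative radiation or rainfall")
        self.frame = df.reset_index(drop=True)

    def __len__(self):
        return len(self.frame)

    def __iter__(self):
        return iter(self.frame.itertuples(index=False))

    def tmean(self) -> np.ndarray:
        return ((self.frame["tmin"] + self.frame["tmax"]) / 2.0).to_numpy()

    def thermal_time(self, t_base: float) -> np.ndarray:
        """Daily thermal-time increments, °Cd, clipped at zero."""
        return np.maximum(0.0, self.tmean() - t_base)

    def slice_days(self, n_days: int) -> "WeatherSeries":
        if n_days > len(self):
            raise ValueError(f"weather gap: need {n_days} days, have {len(self)}")
        return WeatherSeries(self.frame.iloc[:n_days].copy())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return cls(pd.read_csv(path))


def generate_weather(
    n_days: int,
    season_profile: str = "summer",
    seed: int = 0,
    start_date: str = "2016-06-24",
) -> WeatherSeries:
    """Synthesize a plausible temperate daily weather series.

    Temperatures follow the profile mean with AR(1) day-to-day anomalies,
    radiation co-varies negatively with rain, and rain is drawn from a
    mixture of dry days and gamma-distributed wet days.  Deterministic for
    a given (profile, seed).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if season_profile not in PROFILES:
        raise ValueError(f"unknown season profile {season_profile!r}; known: {sorted(PROFILES)}")
    tmean_mu, trange, srad_mu, rain_mu = PROFILES[season_profile]
    rng = np.random.default_rng(seed)

    if season_profile == "constant":
        tmean = np.full(n_days, tmean_mu)
        srad = np.full(n_days, srad_mu)
        rain = np.zeros(n_days)
        trange_arr = np.zeros(n_days)
    else:
        anom = np.empty(n_days)
        anom[0] = rng.normal(0, 2.0)
        for i in range(1, n_days):  # AR(1), rho 0.7
            anom[i] = 0.7 * anom[i - 1] + rng.normal(0, 1.6)
        tmean = tmean_mu + anom
        wet = rng.random(n_days) < 0.35
        rain = np.where(wet, rng.gamma(1.2, rain_mu / (0.35 * 1.2), n_days), 0.0)
        srad = np.clip(srad_mu * (1.0 - 0.35 * wet) + rng.normal(0, 2.0, n_days), 0.5, None)
        trange_arr = np.clip(trange + rng.normal(0, 1.5, n_days), 2.0, None)

    df = pd.DataFrame(
        {
            "date": pd.date_range(start_date, periods=n_days, freq="D"),
            "tmin": tmean - trange_arr / 2.0,
            "tmax": tmean + trange_arr / 2.0,
            "srad": srad,
            "rain": rain,
        }
    )
    return WeatherSeries(df)
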