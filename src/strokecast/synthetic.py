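"""Synthetic daily stroke-count and meteorological series.

The generator emulates the statistical shape of a mid-European district
registry: Poisson-like daily event counts with mean around 2.6 and roughly
7–10 % zero days, weak autocorrelation, optional annual/weekly seasonality,
and meteorological series built from an annual sinusoid plus AR(1) noise.
Lagged meteorological effects on the count intensity can be planted with
chosen log-rate coefficients; the default is no effect, so downstream
association screens should come out null.

Thermal-comfort indices
-----------------------
Three composite indices are derived from temperature ``T`` (°C, daily
mean), relative humidity ``RH`` (%) and wind speed ``v`` (m/s):

* Wind Chill Index (Siple–Passel):
  ``WCI = (10*sqrt(v) + 10.45 - v) * (33 - T)``
* Discomfort Index (Thom):
  ``DI = T - 0.55*(1 - 0.01*RH)*(T - 14.5)``
* Effective temperature accounting for wind (Missenard):
  ``ETV = 37 - (37 - T)/(0.68 - 0.0014*RH + 1/(1.76 + 1.4*v**0.75))
  - 0.29*T*(1 - 0.01*RH)``

These are the standard published forms; national weather services use
slight variants, so each is overridable via ``index_formulas``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data_io import METEO_VARS, ValidationError, validate_counts, validate_meteo

__all__ = [
    "MeteoVarParams", "SyntheticConfig", "compute_indices",
    "generate_meteo", "generate_counts", "generate_dataset",
    "wind_chill_index", "discomfort_index", "effective_temperature",
]


# --------------------------------------------------------------------------
# thermal-comfort indices

def wind_chill_index(t_mean, humidity, wind):
    """Siple–Passel wind chill, W/m² scale: (10√v + 10.45 − v)(33 − T)."""
    v = np.asarray(wind, dtype=float)
    t = np.asarray(t_mean, dtype=float)
    return (10.0 * np.sqrt(v) + 10.45 - v) * (33.0 - t)


def discomfort_index(t_mean, humidity, wind):
    """Thom discomfort index: T − 0.55(1 − 0.01 RH)(T − 14.5)."""
    t = np.asarray(t_mean, dtype=float)
    rh = np.asarray(humidity, dtype=float)
    return t - 0.55 * (1.0 - 0.01 * rh) * (t - 14.5)


def effective_temperature(t_mean, humidity, wind):
    """Missenard effective temperature with a wind term."""
    t = np.asarray(t_mean, dtype=float)
    rh = np.asarray(humidity, dtype=float)
    v = np.asarray(wind, dtype=float)
    denom = 0.68 - 0.0014 * rh + 1.0 / (1.76 + 1.4 * v**0.75)
    return 37.0 - (37.0 - t) / denom - 0.29 * t * (1.0 - 0.01 * rh)


DEFAULT_INDEX_FORMULAS: dict[str, Callable] = {
    "ETV": effective_temperature,
    "WCI": wind_chill_index,
    "DI": discomfort_index,
}


def compute_indices(meteo: pd.DataFrame,
                    formulas: Mapping[str, Callable] | None = None) -> pd.DataFrame:
    """Fill the ETV/WCI/DI columns from t_mean, humidity and wind.

    Existing index columns are recomputed. ``formulas`` may override any of
    the three index callables (signature ``f(t_mean, humidity, wind)``).
    """
    fns = dict(DEFAULT_INDEX_FORMULAS)
    if formulas:
        fns.update(formulas)
    wind = meteo["wind"].to_numpy(dtype=float)
    if np.any(wind[~np.isnan(wind)] < 0):
        raise ValidationError("negative wind speed")
    out = meteo.copy()
    for name, fn in fns.items():
        out[name] = fn(meteo["t_mean"], meteo["humidity"], meteo["wind"])
    return out


# --------------------------------------------------------------------------
# configuration

@dataclass
class MeteoVarParams:
    """Annual-cycle + AR(1) parameters for one meteorological variable."""

    mean: float
    annual_amp: float = 0.0
    ar: float = 0.7
    sd: float = 1.0
    phase: float = 0.0  # fraction of a year; 0 peaks mid-July with the default phase below

    def __post_init__(self):
        if not (0.0 <= self.ar < 1.0):
            raise ValueError(f"AR(1) coefficient must be in [0, 1), got {self.ar}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def _default_meteo_params() -> dict[str, MeteoVarParams]:
    # Rough continental, temperate-belt climatology (mid-latitude Europe):
    # mean T about 10 °C with ±10 °C annual swing, humid ~75 %, water-vapour
    # pressure ~12 hPa tracking temperature, light mean winds.
    return {
        "t_mean": MeteoVarParams(mean=10.0, annual_amp=10.0, ar=0.8, sd=2.5),
        "humidity": MeteoVarParams(mean=75.0, annual_amp=-8.0, ar=0.6, sd=8.0),
        "pressure": MeteoVarParams(mean=12.0, annual_amp=6.0, ar=0.7, sd=1.5),
        "wind": MeteoVarParams(mean=3.5, annual_amp=0.5, ar=0.5, sd=1.5),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic district.

    Defaults mirror the registry the analysis targets: ~2.6 strokes/day,
    no planted trend, seasonality or meteorological effect, Poisson noise.
    ``meteo_effects`` maps variable name -> {lag (days) -> log-rate
    coefficient per 1 SD of the variable}.
    """

    seed: int = 0
    n_days: int = 1826  # five civil years
    start_date: str = "2015-01-01"
    base_rate: float = 2.6
    dispersion: str | float = "poisson"  # or a negative-binomial size theta > 0
    annual_amp: float = 0.0
    weekly_amp: float = 0.0
    trend_slope: float = 0.0
    meteo_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    meteo_params: dict[str, MeteoVarParams] = field(default_factory=_default_meteo_params)
    spread_mean: float = 4.0  # mean half-distance t_max/t_min from t_mean (°C)
    spread_sd: float = 1.2
    wet_day_prob: float = 0.45
    rain_mean: float = 4.0  # mm on wet days
    index_formulas: dict[str, Callable] | None = None

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.dispersion != "poisson" and not (
            isinstance(self.dispersion, (int, float)) and self.dispersion > 0
        ):
            raise ValueError("dispersion must be 'poisson' or a positive number")
        if self.annual_amp < 0 or self.weekly_amp < 0:
            raise ValueError("seasonal amplitudes must be >= 0")

    def calendar(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


# --------------------------------------------------------------------------
# generators

def _ar1(rng: np.random.Generator, n: int, ar: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - ar**2)
    e = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = ar * x[t - 1] + e[t]
    return x


def _annual(dates: pd.DatetimeIndex, amp: float, phase: float = 0.0) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    # peak around day 196 (mid July) when phase == 0
    return amp * np.cos(2.0 * np.pi * (doy / 365.25 - 196.0 / 365.25 - phase))


def generate_meteo(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the eleven-variable meteorological table.

    Each driven variable is an annual cosine plus stationary AR(1) noise;
    daily extremes are ``t_mean`` ± independent positive half-amplitudes,
    humidity is clipped to [0, 100], wind floored at 0.05 m/s,
    precipitation is zero-inflated exponential with an AR(1) latent wet/dry
    process. The comfort indices are filled by :func:`compute_indices`.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.uint32(config.seed))
    dates = config.calendar()
    n = config.n_days
    cols: dict[str, np.ndarray] = {}
    for var in ("t_mean", "humidity", "pressure", "wind"):
        p = config.meteo_params[var]
        cols[var] = p.mean + _annual(dates, p.annual_amp, p.phase) + _ar1(rng, n, p.ar, p.sd)
    cols["humidity"] = np.clip(cols["humidity"], 0.0, 100.0)
    cols["pressure"] = np.maximum(cols["pressure"], 0.1)
    cols["wind"] = np.maximum(cols["wind"], 0.05)
    up = np.abs(rng.normal(config.spread_mean, config.spread_sd, size=n))
    dn = np.abs(rng.normal(config.spread_mean, config.spread_sd, size=n))
    cols["t_max"] = cols["t_mean"] + up
    cols["t_min"] = cols["t_mean"] - dn
    cols["t_ampl"] = cols["t_max"] - cols["t_min"]
    wet_latent = _ar1(rng, n, 0.5, 1.0)
    wet = wet_latent > np.quantile(wet_latent, 1.0 - config.wet_day_prob)
    amounts = rng.exponential(config.rain_mean, size=n)
    cols["precipitation"] = np.where(wet, amounts, 0.0)
    table = pd.DataFrame(cols, index=dates)
    table = compute_indices(table, config.index_formulas)
    table = table[METEO_VARS]
    table.index.name = "date"
    return validate_meteo(table)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def log_intensity(config: SyntheticConfig, meteo: pd.DataFrame) -> np.ndarray:
    """Daily log intensity of the count process (before noise)."""
    dates = config.calendar()
    n = config.n_days
    eta = np.full(n, np.log(config.base_rate))
    if config.annual_amp:
        eta += _annual(dates, config.annual_amp)
    if config.weekly_amp:
        dow = dates.dayofweek.to_numpy(dtype=float)
        eta += config.weekly_amp * np.cos(2.0 * np.pi * dow / 7.0)
    if config.trend_slope:
        eta += config.trend_slope * np.arange(n)
    for var, lag_map in config.meteo_effects.items():
        if var not in meteo.columns:
            raise ValueError(f"meteo_effects refers to unknown variable {var!r}")
        z = _standardize(meteo[var].to_numpy(dtype=float)[:n])
        for lag, coef in lag_map.items():
            lag = int(lag)
            if lag < 0:
                raise ValueError("meteo effect lags must be >= 0")
            if lag == 0:
                shifted = z
            else:
                shifted = np.zeros(n)
                shifted[lag:] = z[: n - lag]
            eta += float(coef) * shifted
    return eta


def generate_counts(config: SyntheticConfig, meteo: pd.DataFrame) -> pd.Series:
    """Simulate the daily stroke-count series given a meteorological table.

    Counts are Poisson (or gamma-mixed Poisson, i.e. negative binomial with
    size ``dispersion``) with log intensity = log(base_rate) + seasonal
    terms + trend + Σ coef · (standardized lagged meteo). Deterministic for
    a fixed seed; the count stream is independent of the meteo stream's
    draws (separate bit generator).
    """
    if len(meteo) < config.n_days:
        raise ValueError(
            f"meteo table covers {len(meteo)} days < n_days={config.n_days}"
        )
    rng = np.random.default_rng(np.uint32(config.seed) + np.uint32(2**20))
    mu = np.exp(log_intensity(config, meteo))
    if config.dispersion == "poisson":
        counts = rng.poisson(mu)
    else:
        theta = float(config.dispersion)
        gamma = rng.gamma(theta, 1.0 / theta, size=config.n_days)
        counts = rng.poisson(mu * gamma)
    series = pd.Series(counts.astype(float), index=config.calendar(), name="count")
    series.index.name = "date"
    return validate_counts(series)


def generate_dataset(config: SyntheticConfig) -> tuple[pd.Series, pd.DataFrame]:
    """Convenience: one call producing (counts, meteo) for a config."""
    meteo = generate_meteo(config)
    counts = generate_counts(config, meteo)
    return counts, meteo
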