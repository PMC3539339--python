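"""Dynamic forcing series: synthesis, CSV I/O and zero-order-hold sampling.

The model is driven by fifteen time-varying parameters at three native
resolutions:

* hourly — water depth ``h2`` (m);
* daily — temperature ``T`` (degC), wind speed ``WS`` (m/s), rain rate
  ``Kw`` (m/h) and the interface coefficients ``K12``/``K21``/``K42r``
  (m/h, derived from wind and depth unless supplied);
* monthly — aerosol and suspended-solid volume fractions ``X13``/``X23``,
  advection volumes ``Q01t``/``Q10t``/``Q02t``/``Q20t``/``Q23h``/``Q02h``
  (m3/h) and the carried concentrations ``C1`` (background air, mol/m3)
  and ``C02t`` (river inflow, mol/m3).

Coarser series are applied stepwise (zero-order hold) on the hourly solver
axis — each hour reads the value of the day or month containing it — which
keeps daily and monthly budgets exact.  The synthetic generator emulates a
temperate-lake seasonal cycle: sinusoidal temperature with daily noise, a
positive lognormal AR(1) wind process, seasonally modulated water depth and
rain, and monthly lognormal draws for advection volumes, particle fractions
and background concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ChemicalProperties
from .transfer import TransferConstants, k12_air_side, k21_water_side, k42r_resuspension

__all__ = [
    "ForcingValidationError",
    "GeneratorConfig",
    "ForcingSet",
    "generate_forcings",
    "load_forcings",
    "save_forcings",
    "sample_at",
]

HOURLY_SERIES = ("h2",)
DAILY_SERIES = ("temperature", "wind_speed", "rain_rate", "k12", "k21", "k42r")
MONTHLY_SERIES = (
    "aerosol_fraction",
    "suspended_fraction",
    "q01t",
    "q10t",
    "q02t",
    "q20t",
    "q23h",
    "q02h",
    "c_air_in",
    "c_water_in",
    "c_wastewater",
)
#: Series that may be negative (everything else must be >= 0).
_SIGNED = ("temperature",)


class ForcingValidationError(ValueError):
    """A forcing series has gaps, wrong length or physically invalid values."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic forcing generator.

    The defaults describe a large shallow eutrophic lake in a subtropical
    monsoon climate (annual mean air temperature about 16 degC, summer
    temperature and rainfall maxima, mean wind near 3 m/s) with advection
    volumes and background concentrations representative of a rural
    organochlorine-legacy airshed.  Monthly quantities are drawn lognormal
    around the stated medians with the stated geometric SDs.
    """

    temp_mean: float = 16.0  # degC, annual mean
    temp_amplitude: float = 13.0  # degC, seasonal half-range
    temp_peak_doy: int = 205  # day of year of the warmest day (late July)
    temp_noise_sd: float = 2.0  # degC, daily Gaussian noise
    wind_median: float = 2.8  # m/s
    wind_log_sd: float = 0.35  # log-scale SD of the AR(1) process
    wind_ar: float = 0.7  # day-to-day autocorrelation
    h2_base: float = 3.0124  # m, annual mean water depth
    h2_amplitude: float = 0.30  # m, seasonal half-range (summer maximum)
    h2_noise_sd: float = 0.005  # m, hourly jitter
    h2_min: float = 0.5  # m, hard floor
    rain_median: float = 8e-5  # m/h (~0.7 m/a at the median)
    rain_log_sd: float = 0.9
    rain_summer_factor: float = 2.0  # multiplicative summer enhancement
    monthly_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "aerosol_fraction": 7.6278e-11,
            "suspended_fraction": 1.2631e-5,
            "q01t": 2.0e10,  # air advection, m3/h
            "q10t": 2.0e10,
            "q02t": 4.0e5,  # river inflow, m3/h
            "q20t": 4.0e5,
            "q23h": 2.0e4,  # industrial/agricultural withdrawal
            "q02h": 1.0e3,  # wastewater discharge volume
            "c_air_in": 5.5e-14,  # mol/m3 (~16 pg/m3)
            "c_water_in": 3.0e-9,  # mol/m3 (~870 pg/L)
            "c_wastewater": 0.0,
        }
    )
    monthly_gsd: Mapping[str, float] = field(
        default_factory=lambda: {
            "aerosol_fraction": 1.3,
            "suspended_fraction": 1.3,
            "q01t": 1.3,
            "q10t": 1.3,
            "q02t": 1.6,
            "q20t": 1.6,
            "q23h": 1.4,
            "q02h": 1.4,
            "c_air_in": 1.5,
            "c_water_in": 1.5,
            "c_wastewater": 1.0,
        }
    )
    #: air advection in and out track each other (bulk air volume balance)
    tie_air_advection: bool = True


@dataclass(frozen=True)
class ForcingSet:
    """Aligned forcing series over a simulation window.

    ``hours`` is the hourly DatetimeIndex of the window; ``h2`` matches it.
    ``daily`` and ``monthly`` are DataFrames indexed by day and by month
    period with the columns listed in :data:`DAILY_SERIES` and
    :data:`MONTHLY_SERIES`.
    """

    hours: pd.DatetimeIndex
    h2: np.ndarray
    daily: pd.DataFrame
    monthly: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.hours)
        if n == 0:
            raise ForcingValidationError("empty simulation window")
        if n % 24 != 0:
            raise ForcingValidationError(f"window must span whole days, got {n} hours")
        if len(self.h2) != n:
            raise ForcingValidationError(
                f"h2 has {len(self.h2)} values for {n} hours"
            )
        if len(self.daily) != n // 24:
            raise ForcingValidationError(
                f"daily table has {len(self.daily)} rows for {n // 24} days"
            )
        expected_months = self.hours.to_period("M").unique()
        if not self.monthly.index.equals(pd.PeriodIndex(expected_months)):
            missing = expected_months.difference(self.monthly.index)
            raise ForcingValidationError(
                f"monthly table does not match window months; missing {list(missing)}"
            )
        for name in DAILY_SERIES:
            if name not in self.daily.columns:
                raise ForcingValidationError(f"daily series '{name}' missing")
        for name in MONTHLY_SERIES:
            if name not in self.monthly.columns:
                raise ForcingValidationError(f"monthly series '{name}' missing")
        self._check_values()
        # positional lookup tables for zero-order hold
        object.__setattr__(self, "_day_of_hour", np.arange(n) // 24)
        month_codes = self.monthly.index.get_indexer(self.hours.to_period("M"))
        object.__setattr__(self, "_month_of_hour", month_codes)

    def _check_values(self) -> None:
        bad: list[str] = []
        if np.any(~np.isfinite(self.h2)):
            bad.append("h2 contains non-finite values")
        elif np.any(self.h2 <= 0):
            bad.append("h2 must be > 0 throughout")
        for frame, names in ((self.daily, DAILY_SERIES), (self.monthly, MONTHLY_SERIES)):
            for name in names:
                col = frame[name].to_numpy(dtype=float)
                if np.any(~np.isfinite(col)):
                    bad.append(f"{name} contains gaps/non-finite values")
                elif name not in _SIGNED and np.any(col < 0):
                    bad.append(f"{name} contains negative values")
        if bad:
            raise ForcingValidationError("; ".join(bad))

    @property
    def n_hours(self) -> int:
        return len(self.hours)

    def snapshot(self, t: int) -> dict[str, float]:
        """All forcing values holding at hour index ``t`` (zero-order hold)."""
        if not 0 <= t < self.n_hours:
            raise IndexError(f"hour index {t} outside window of {self.n_hours} hours")
        day = self._day_of_hour[t]
        month = self._month_of_hour[t]
        out = {"h2": float(self.h2[t])}
        for name in DAILY_SERIES:
            out[name] = float(self.daily[name].iloc[day])
        for name in MONTHLY_SERIES:
            out[name] = float(self.monthly[name].iloc[month])
        return out

    def expand_hourly(self) -> pd.DataFrame:
        """All series on the hourly axis via zero-order hold (solver input)."""
        data = {"h2": np.asarray(self.h2, dtype=float)}
        for name in DAILY_SERIES:
            data[name] = self.daily[name].to_numpy(dtype=float)[self._day_of_hour]
        for name in MONTHLY_SERIES:
            data[name] = self.monthly[name].to_numpy(dtype=float)[self._month_of_hour]
        return pd.DataFrame(data, index=self.hours)

    def month_of_hour(self) -> np.ndarray:
        """Positional month index (0-based within the window) per hour."""
        return np.asarray(self._month_of_hour)

    def month_labels(self) -> list[str]:
        return [str(p) for p in self.monthly.index]


def _window_index(start: str | pd.Timestamp, end: str | pd.Timestamp) -> pd.DatetimeIndex:
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end < start:
        raise ForcingValidationError(f"window end {end.date()} precedes start {start.date()}")
    # inclusive of the whole end day
    return pd.date_range(start, end + pd.Timedelta(days=1), freq="h", inclusive="left")


def generate_forcings(
    seed: int,
    start: str | pd.Timestamp = "2010-05-01",
    end: str | pd.Timestamp = "2011-02-28",
    config: GeneratorConfig | None = None,
    chem: ChemicalProperties | None = None,
    constants: TransferConstants | None = None,
) -> ForcingSet:
    """Synthesize a complete, reproducible forcing set for the window.

    ``chem`` (for the molar mass) and ``constants`` (for the surface-flow
    velocity) feed the derived interface coefficients K12/K21/K42r; when
    omitted, defaults for a 290.83 g/mol chemical are used.
    """
    cfg = config or GeneratorConfig()
    molar_mass = chem.molar_mass if chem is not None else 290.83
    surface_flow = (constants or TransferConstants()).surface_flow
    rng = np.random.default_rng(seed)

    hours = _window_index(start, end)
    days = pd.date_range(hours[0], periods=len(hours) // 24, freq="D")
    months = pd.period_range(hours[0], hours[-1], freq="M")
    doy = days.dayofyear.to_numpy(dtype=float)
    seasonal = np.cos(2.0 * np.pi * (doy - cfg.temp_peak_doy) / 365.0)

    temperature = (
        cfg.temp_mean
        + cfg.temp_amplitude * seasonal
        + rng.normal(0.0, cfg.temp_noise_sd, len(days))
    )

    # wind: AR(1) on the log scale keeps the series positive and autocorrelated
    n_days = len(days)
    log_wind = np.empty(n_days)
    innovation_sd = cfg.wind_log_sd * np.sqrt(max(1.0 - cfg.wind_ar**2, 1e-12))
    log_wind[0] = np.log(cfg.wind_median) + rng.normal(0.0, cfg.wind_log_sd)
    for i in range(1, n_days):
        log_wind[i] = (
            np.log(cfg.wind_median)
            + cfg.wind_ar * (log_wind[i - 1] - np.log(cfg.wind_median))
            + rng.normal(0.0, innovation_sd)
        )
    wind = np.exp(log_wind)

    rain = np.exp(rng.normal(np.log(cfg.rain_median), cfg.rain_log_sd, n_days))
    rain *= 1.0 + (cfg.rain_summer_factor - 1.0) * np.clip(seasonal, 0.0, None)

    hourly_seasonal = np.repeat(seasonal, 24)
    h2 = (
        cfg.h2_base
        + cfg.h2_amplitude * hourly_seasonal
        + rng.normal(0.0, cfg.h2_noise_sd, len(hours))
    )
    h2 = np.maximum(h2, cfg.h2_min)

    h2_daily = h2.reshape(-1, 24).mean(axis=1)
    k12 = np.array([k12_air_side(w, surface_flow, molar_mass) for w in wind])
    k21 = np.array(
        [k21_water_side(w, surface_flow, molar_mass, h) for w, h in zip(wind, h2_daily)]
    )
    k42r = np.array([k42r_resuspension(w, h) for w, h in zip(wind, h2_daily)])

    monthly = {}
    for name in MONTHLY_SERIES:
        median = cfg.monthly_medians.get(name, 0.0)
        gsd = cfg.monthly_gsd.get(name, 1.0)
        if median <= 0.0 or gsd <= 1.0:
            monthly[name] = np.full(len(months), median)
        else:
            monthly[name] = np.exp(
                rng.normal(np.log(median), np.log(gsd), len(months))
            )
    if cfg.tie_air_advection:
        monthly["q10t"] = monthly["q01t"].copy()

    daily = pd.DataFrame(
        {
            "temperature": temperature,
            "wind_speed": wind,
            "rain_rate": rain,
            "k12": k12,
            "k21": k21,
            "k42r": k42r,
        },
        index=days,
    )
    return ForcingSet(
        hours=hours,
        h2=h2,
        daily=daily,
        monthly=pd.DataFrame(monthly, index=months),
    )


def sample_at(forcing: ForcingSet, t: int) -> dict[str, float]:
    """Snapshot of all forcing values holding at hour index ``t``."""
    return forcing.snapshot(t)


def save_forcings(forcing: ForcingSet, directory: str | Path) -> dict[str, Path]:
    """Write one ``timestamp,value`` CSV per series; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, index, values) -> None:
        path = directory / f"{name}.csv"
        pd.DataFrame({"timestamp": index, "value": values}).to_csv(path, index=False)
        paths[name] = path

    _write("h2", forcing.hours, forcing.h2)
    for name in DAILY_SERIES:
        _write(name, forcing.daily.index, forcing.daily[name].to_numpy())
    for name in MONTHLY_SERIES:
        _write(
            name,
            forcing.monthly.index.to_timestamp(),
            forcing.monthly[name].to_numpy(),
        )
    return paths


def _read_series(path: Path, name: str) -> pd.Series:
    frame = pd.read_csv(path)
    if "timestamp" not in frame.columns or "value" not in frame.columns:
        raise ForcingValidationError(
            f"{name}: expected columns 'timestamp' and 'value' in {path}"
        )
    idx = pd.to_datetime(frame["timestamp"])
    return pd.Series(frame["value"].to_numpy(dtype=float), index=pd.DatetimeIndex(idx))


def load_forcings(
    paths: Mapping[str, str | Path] | str | Path,
    start: str | pd.Timestamp = "2010-05-01",
    end: str | pd.Timestamp = "2011-02-28",
    chem: ChemicalProperties | None = None,
    constants: TransferConstants | None = None,
) -> ForcingSet:
    """Load forcing CSVs (one per series, or a directory of ``<name>.csv``).

    Every series must cover the window contiguously at its native
    resolution; gaps raise :class:`ForcingValidationError` naming the
    missing periods.  K12/K21/K42r files are optional — when absent they
    are derived from wind speed and daily-mean water depth.
    """
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        paths = {
            p.stem: p
            for p in directory.glob("*.csv")
            if p.stem in HOURLY_SERIES + DAILY_SERIES + MONTHLY_SERIES
        }
    paths = dict(paths)

    hours = _window_index(start, end)
    days = pd.date_range(hours[0], periods=len(hours) // 24, freq="D")
    months = pd.period_range(hours[0], hours[-1], freq="M")

    def _require(name: str, expected: pd.Index, label: str) -> np.ndarray:
        if name not in paths:
            raise ForcingValidationError(f"no CSV supplied for required series '{name}'")
        series = _read_series(Path(paths[name]), name)
        missing = expected.difference(series.index)
        if len(missing):
            shown = ", ".join(str(m)[:10] for m in missing[:5])
            raise ForcingValidationError(
                f"{name}: {len(missing)} missing {label} value(s), first: {shown}"
            )
        return series.reindex(expected).to_numpy(dtype=float)

    h2 = _require("h2", hours, "hourly")
    daily = pd.DataFrame(index=days)
    for name in ("temperature", "wind_speed", "rain_rate"):
        daily[name] = _require(name, days, "daily")
    derivable = {"k12", "k21", "k42r"}
    for name in derivable:
        if name in paths:
            daily[name] = _require(name, days, "daily")
    if not derivable.issubset(daily.columns):
        molar_mass = chem.molar_mass if chem is not None else 290.83
        rs = (constants or TransferConstants()).surface_flow
        h2_daily = h2.reshape(-1, 24).mean(axis=1)
        wind = daily["wind_speed"].to_numpy()
        if "k12" not in daily.columns:
            daily["k12"] = [k12_air_side(w, rs, molar_mass) for w in wind]
        if "k21" not in daily.columns:
            daily["k21"] = [
                k21_water_side(w, rs, molar_mass, h) for w, h in zip(wind, h2_daily)
            ]
        if "k42r" not in daily.columns:
            daily["k42r"] = [k42r_resuspension(w, h) for w, h in zip(wind, h2_daily)]

    monthly = pd.DataFrame(index=months)
    month_starts = months.to_timestamp()
    for name in MONTHLY_SERIES:
        if name not in paths and name in ("q02h", "c_wastewater"):
            monthly[name] = 0.0  # optional wastewater terms default to zero
            continue
        monthly[name] = _require(name, month_starts, "monthly")

    return ForcingSet(
        hours=hours, h2=h2, daily=daily[list(DAILY_SERIES)], monthly=monthly
    )
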