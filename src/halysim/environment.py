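"""Abiotic drivers: day length, daily temperature series, degree-day arithmetic.

Day length is computed from latitude and day of year with the CBM model of
Forsythe et al. (1995), parameterized by a *daylength coefficient* ``p`` (degrees)
that sets the sun-position angle bounding "daylight". ``p = 0.8333`` corresponds
to the sun's upper limb at the horizon with standard atmospheric refraction.

Temperatures come either from a GHCN-Daily-style CSV (``read_weather_csv``) or
from a synthetic generator (``synthesize_weather``) that superimposes AR(1)
noise on a sinusoidal annual cycle. Degree-days use the daily average method
with a lower base and an optional horizontal upper cutoff.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteProfile",
    "SyntheticClimateSpec",
    "WeatherSeries",
    "day_length",
    "photoperiod_window",
    "degree_days",
    "read_weather_csv",
    "synthesize_weather",
    "write_weather_csv",
]

logger = logging.getLogger(__name__)

#: Default daylength coefficient (degrees): sun's upper limb + standard refraction.
DEFAULT_DAYLENGTH_COEFFICIENT = 0.8333

#: Latitude band (degrees) within which the CBM model never hits polar day/night.
MAX_ABS_LATITUDE = 66.0


@dataclass(frozen=True)
class SiteProfile:
    """A simulation site; only the latitude enters the computation.

    Longitude is carried as metadata (site registries print it) but plays no
    role: photoperiod depends on latitude and day of year only, and weather is
    supplied per site.
    """

    name: str
    latitude: float
    longitude: float | None = None

    def __post_init__(self) -> None:
        if not (-MAX_ABS_LATITUDE <= self.latitude <= MAX_ABS_LATITUDE):
            raise ValueError(
                f"latitude {self.latitude} outside supported band "
                f"[-{MAX_ABS_LATITUDE}, {MAX_ABS_LATITUDE}]"
            )


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Parameters of the synthetic annual temperature cycle.

    ``tmean(d) = annual_mean - annual_amplitude * cos(2*pi*(d - phase_day + 182.5)/365) + AR(1) noise``

    so the warmest expected day is ``phase_day``. ``tmin``/``tmax`` are placed
    symmetrically ``diurnal_range/2`` below/above ``tmean``. Noise is an AR(1)
    process with marginal standard deviation ``noise_sd`` and lag-1
    autocorrelation ``noise_autocorrelation``.
    """

    annual_mean: float = 12.0
    annual_amplitude: float = 14.0
    diurnal_range: float = 10.0
    noise_sd: float = 3.0
    noise_autocorrelation: float = 0.6
    phase_day: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0:
            raise ValueError("annual_amplitude must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.noise_autocorrelation < 1):
            raise ValueError("noise_autocorrelation must be in [0, 1)")


def day_length(
    latitude: float,
    day_of_year: int | np.ndarray,
    daylength_coefficient: float = DEFAULT_DAYLENGTH_COEFFICIENT,
) -> float | np.ndarray:
    """Hours of daylight at ``latitude`` on ``day_of_year`` (CBM model).

    Revolution angle  theta = 0.2163108 + 2*atan(0.9671396*tan(0.00860*(J-186)))
    Declination       phi   = asin(0.39795*cos(theta))
    Day length        D     = 24 - (24/pi)*acos[(sin(p') + sin(L')*sin(phi)) /
                                                (cos(L')*cos(phi))]

    with ``p'``, ``L'`` the daylength coefficient and latitude in radians.
    Accepts a scalar or array ``day_of_year``; no leap correction is applied
    (the formula is defined on J directly).
    """
    if not (-MAX_ABS_LATITUDE <= latitude <= MAX_ABS_LATITUDE):
        raise ValueError(f"latitude {latitude} outside [-66, 66]")
    j = np.asarray(day_of_year, dtype=float)
    if np.any(j < 1) or np.any(j > 366):
        raise ValueError("day_of_year must be in 1..366")
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (j - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))
    lat = math.radians(latitude)
    p = math.radians(daylength_coefficient)
    cos_arg = (math.sin(p) + math.sin(lat) * np.sin(phi)) / (math.cos(lat) * np.cos(phi))
    if np.any(cos_arg < -1.0) or np.any(cos_arg > 1.0):
        bad = np.atleast_1d(j)[np.atleast_1d((cos_arg < -1) | (cos_arg > 1))]
        raise ValueError(
            f"polar day/night condition at latitude {latitude} on day(s) {bad[:3]}"
        )
    d = 24.0 - (24.0 / math.pi) * np.arccos(cos_arg)
    return float(d) if np.isscalar(day_of_year) else d


def _days_in_year(year: int) -> int:
    return 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365


def photoperiod_window(
    latitude: float,
    year: int,
    critical_hours: float,
    daylength_coefficient: float = DEFAULT_DAYLENGTH_COEFFICIENT,
) -> tuple[dt.date, dt.date] | None:
    """First and last calendar dates with day length >= ``critical_hours``.

    Returns ``None`` when no day of the year qualifies (e.g. a 14.0 h
    threshold at Homestead FL's latitude).
    """
    if not (0 < critical_hours < 24):
        raise ValueError("critical_hours must be in (0, 24)")
    n = _days_in_year(year)
    j = np.arange(1, n + 1)
    d = day_length(latitude, j, daylength_coefficient)
    qualifying = j[d >= critical_hours]
    if qualifying.size == 0:
        return None
    start = dt.date(year, 1, 1)
    return (
        start + dt.timedelta(days=int(qualifying[0]) - 1),
        start + dt.timedelta(days=int(qualifying[-1]) - 1),
    )


def degree_days(
    tmin: float | np.ndarray,
    tmax: float | np.ndarray,
    base: float,
    upper: float | None = None,
) -> float | np.ndarray:
    """Daily degree-days by the average method.

    ``DD = max(0, min(tmean, upper) - base)`` with ``tmean = (tmin + tmax)/2``.
    ``upper=None`` means no ceiling. Never negative.
    """
    if upper is not None and base >= upper:
        raise ValueError(f"base {base} must be below upper cutoff {upper}")
    tmin_a = np.asarray(tmin, dtype=float)
    tmax_a = np.asarray(tmax, dtype=float)
    if np.any(tmin_a > tmax_a):
        raise ValueError("tmin must not exceed tmax")
    tmean = (tmin_a + tmax_a) / 2.0
    if upper is not None:
        tmean = np.minimum(tmean, upper)
    dd = np.maximum(0.0, tmean - base)
    return float(dd) if np.isscalar(tmin) and np.isscalar(tmax) else dd


class WeatherSeries:
    """One site-year of daily weather with derived photoperiod and DD caches.

    ``days`` is a DataFrame with one row per calendar day Jan 1 - Dec 31
    (columns ``date``, ``tmin``, ``tmax``, ``tmean``); ``photoperiod`` is the
    matching array of day lengths (hours) for the site latitude. Degree-day
    increment arrays are cached per ``(base, upper)`` pair.
    """

    def __init__(
        self,
        site: SiteProfile,
        year: int,
        days: pd.DataFrame,
        daylength_coefficient: float = DEFAULT_DAYLENGTH_COEFFICIENT,
    ) -> None:
        expected = _days_in_year(year)
        if len(days) != expected:
            raise ValueError(
                f"weather for {site.name} {year} has {len(days)} days, expected {expected}"
            )
        dates = pd.to_datetime(days["date"])
        if dates.iloc[0] != pd.Timestamp(year, 1, 1) or dates.iloc[-1] != pd.Timestamp(year, 12, 31):
            raise ValueError("weather series must cover Jan 1 - Dec 31")
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError("dates must be strictly increasing, one per day")
        if (days["tmin"] > days["tmax"]).any():
            raise ValueError("tmin > tmax in weather series")
        self.site = site
        self.year = year
        self.days = days.reset_index(drop=True).copy()
        self.days["date"] = dates.dt.date.values
        self.days["tmean"] = (self.days["tmin"] + self.days["tmax"]) / 2.0
        self.daylength_coefficient = daylength_coefficient
        self.tmin = self.days["tmin"].to_numpy(float)
        self.tmax = self.days["tmax"].to_numpy(float)
        self.tmean = self.days["tmean"].to_numpy(float)
        self.photoperiod = day_length(
            site.latitude, np.arange(1, expected + 1), daylength_coefficient
        )
        self._dd_cache: dict[tuple[float, float | None], np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.days)

    def doy_of(self, date: dt.date) -> int:
        if date.year != self.year:
            raise ValueError(f"{date} outside series year {self.year}")
        return date.timetuple().tm_yday

    def dd_increments(self, base: float, upper: float | None = None) -> np.ndarray:
        """Daily DD increments for the whole year, cached per (base, upper)."""
        key = (base, upper)
        if key not in self._dd_cache:
            self._dd_cache[key] = degree_days(self.tmin, self.tmax, base, upper)
        return self._dd_cache[key]

    def accumulate_degree_days(
        self,
        base: float,
        upper: float | None = None,
        start_date: dt.date | None = None,
        end_date: dt.date | None = None,
    ) -> float:
        """Sum of daily DD over the inclusive [start_date, end_date] window."""
        inc = self.dd_increments(base, upper)
        i0 = self.doy_of(start_date) - 1 if start_date is not None else 0
        i1 = self.doy_of(end_date) - 1 if end_date is not None else len(inc) - 1
        if i0 > i1:
            raise ValueError("start_date after end_date")
        return float(inc[i0 : i1 + 1].sum())

    def checksum(self) -> str:
        """Hash of the temperature arrays, for run manifests."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.tmin).tobytes())
        h.update(np.ascontiguousarray(self.tmax).tobytes())
        return h.hexdigest()[:16]


def accumulate_degree_days(
    series: WeatherSeries,
    base: float,
    upper: float | None = None,
    start_date: dt.date | None = None,
    end_date: dt.date | None = None,
) -> float:
    """Functional alias for :meth:`WeatherSeries.accumulate_degree_days`."""
    return series.accumulate_degree_days(base, upper, start_date, end_date)


def read_weather_csv(
    path,
    site: SiteProfile,
    year: int,
    *,
    date_col: str = "date",
    tmin_col: str = "tmin",
    tmax_col: str = "tmax",
    tenths: bool = False,
    max_gap_days: int = 5,
    daylength_coefficient: float = DEFAULT_DAYLENGTH_COEFFICIENT,
) -> WeatherSeries:
    """Read a GHCN-Daily-style CSV into a :class:`WeatherSeries`.

    Expects ISO-8601 dates and temperatures in deg C (``tenths=True`` divides
    by 10 for raw GHCN extracts). Missing days up to ``max_gap_days`` long are
    filled by linear interpolation (logged); longer gaps raise.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    for col in (date_col, tmin_col, tmax_col):
        if col not in raw.columns:
            raise ValueError(f"weather CSV missing column {col!r}")
    for col in (tmin_col, tmax_col):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"non-numeric temperature in column {col!r} at file row {row}"
            )
        raw[col] = coerced
    raw[date_col] = pd.to_datetime(raw[date_col])
    raw = raw[raw[date_col].dt.year == year].sort_values(date_col)
    full = pd.DataFrame(
        {"date": pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")}
    )
    merged = full.merge(
        raw[[date_col, tmin_col, tmax_col]].rename(
            columns={date_col: "date", tmin_col: "tmin", tmax_col: "tmax"}
        ),
        on="date",
        how="left",
    )
    missing = merged["tmin"].isna() | merged["tmax"].isna()
    if missing.any():
        # longest run of consecutive missing days
        runs = (missing != missing.shift()).cumsum()
        gap = int(missing.groupby(runs).sum().max())
        if gap > max_gap_days:
            raise ValueError(
                f"weather gap of {gap} days exceeds limit {max_gap_days} "
                f"for {site.name} {year}"
            )
        logger.warning(
            "interpolating %d missing day(s) in %s %d weather",
            int(missing.sum()), site.name, year,
        )
        merged[["tmin", "tmax"]] = merged[["tmin", "tmax"]].interpolate(
            method="linear", limit_direction="both"
        )
    if tenths:
        merged[["tmin", "tmax"]] /= 10.0
    return WeatherSeries(site, year, merged, daylength_coefficient)


def write_weather_csv(series: WeatherSeries, path) -> None:
    """Write a series back to the CSV dialect ``read_weather_csv`` accepts."""
    out = series.days[["date", "tmin", "tmax"]].copy()
    out.to_csv(path, index=False)


def synthesize_weather(
    spec: SyntheticClimateSpec,
    site: SiteProfile,
    year: int,
    daylength_coefficient: float = DEFAULT_DAYLENGTH_COEFFICIENT,
) -> WeatherSeries:
    """Generate one site-year of synthetic weather, reproducible from the seed.

    The seasonal cycle is sinusoidal with the warmest expected day at
    ``spec.phase_day``; AR(1) noise with the requested marginal SD and lag-1
    autocorrelation is added to the daily mean, and tmin/tmax straddle it by
    half the diurnal range.
    """
    n = _days_in_year(year)
    d = np.arange(1, n + 1, dtype=float)
    seasonal = spec.annual_mean - spec.annual_amplitude * np.cos(
        2.0 * math.pi * (d - spec.phase_day + 182.5) / 365.0
    )
    rng = np.random.default_rng(spec.seed)
    noise = np.zeros(n)
    if spec.noise_sd > 0:
        rho = spec.noise_autocorrelation
        innov_sd = spec.noise_sd * math.sqrt(1.0 - rho * rho)
        eps = rng.normal(0.0, 1.0, n)
        noise[0] = eps[0] * spec.noise_sd
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + innov_sd * eps[i]
    tmean = seasonal + noise
    half = spec.diurnal_range / 2.0
    days = pd.DataFrame(
        {
            "date": pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D"),
            "tmin": tmean - half,
            "tmax": tmean + half,
        }
    )
    return WeatherSeries(site, year, days, daylength_coefficient)
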