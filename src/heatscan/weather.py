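"""Exposure metrics and case-crossover calendar machinery.

This module holds the building blocks of the time-stratified case-crossover
design as applied to hot-weather mortality:

* the humidex, Canada's standard apparent-temperature index, computed from
  air temperature and dew point;
* aggregation of hourly station observations into daily summaries (mean and
  maximum air temperature and humidex);
* identification of "extremely hot days" as exceedances of a high empirical
  percentile of the daily mean air temperature over the full study series;
* time-stratified referent (control-day) selection: all calendar days in the
  same month and year that share the case day's weekday.

All exposure is measured at a single fixed reference station; no spatial
interpolation of weather is performed here.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "HourlyObservation",
    "ExtremeDaySet",
    "vapour_pressure",
    "compute_humidex",
    "daily_aggregate",
    "identify_extreme_days",
    "referent_days",
    "stratum_key",
    "read_hourly_csv",
    "read_daily_csv",
    "DAILY_COLUMNS",
]

#: canonical column layout of a daily summary frame (one row per station-day)
DAILY_COLUMNS = [
    "date",
    "weekday",
    "mean_air_temp",
    "mean_humidex",
    "max_humidex",
    "n_hours_used",
]

# Humidex constants (Environment Canada formulation).  The dew-point term is
# the saturation vapour pressure at the dew point, in hPa, from the
# Clausius-Clapeyron integration anchored at the triple point of water.
_E_REF_HPA = 6.11
_E_EXP_K = 5417.7530
_T_TRIPLE_K = 273.16
_C_TO_K = 273.15
_HUMIDEX_SCALE = 0.5555  # degrees of apparent temperature per hPa excess over 10


@dataclass(frozen=True)
class HourlyObservation:
    """One hourly station record: timestamp plus air and dew-point temperature (degC)."""

    timestamp: dt.datetime
    air_temp: float
    dew_point: float


@dataclass(frozen=True)
class ExtremeDaySet:
    """Days at or above a high percentile of daily mean air temperature.

    ``threshold`` is the empirical quantile of ``mean_air_temp`` over the
    *entire* daily series; ``dates`` holds every day whose mean air
    temperature is at or above it.
    """

    percentile: float
    threshold: float
    dates: frozenset = field(default_factory=frozenset)

    def __contains__(self, d: dt.date) -> bool:
        return d in self.dates


def vapour_pressure(dew_point_c):
    """Saturation vapour pressure (hPa) at the dew point (degC)."""
    dew_k = np.asarray(dew_point_c, dtype=float) + _C_TO_K
    return _E_REF_HPA * np.exp(_E_EXP_K * (1.0 / _T_TRIPLE_K - 1.0 / dew_k))


def compute_humidex(air_temp, dew_point):
    """Humidex (degC) from air temperature and dew point, both in degC.

    ``H = Ta + 0.5555 * (e - 10)`` where ``e`` is the vapour pressure at the
    dew point in hPa.  The adjustment is positive exactly when ``e > 10`` hPa
    (a dew point of roughly 7 degC); in dry air the humidex is *below* the
    air temperature and is deliberately not clipped.

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input or
    a dew point above 60 degC (far outside physical range).
    """
    ta = np.asarray(air_temp, dtype=float)
    td = np.asarray(dew_point, dtype=float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(td))):
        raise ValueError("compute_humidex: inputs must be finite")
    if np.any(td > 60.0):
        raise ValueError("compute_humidex: dew point above 60 degC is not physical")
    h = ta + _HUMIDEX_SCALE * (vapour_pressure(td) - 10.0)
    if np.isscalar(air_temp) and np.isscalar(dew_point):
        return float(h)
    return h


def daily_aggregate(
    observations,
    min_hours: int = 18,
    humidex_from_hourly: bool = True,
) -> pd.DataFrame:
    """Collapse hourly observations into one row per calendar day.

    Parameters
    ----------
    observations
        Either a DataFrame with columns ``timestamp`` (datetime-like),
        ``air_temp_c`` and ``dew_point_c``, or an iterable of
        :class:`HourlyObservation`.
    min_hours
        Days with fewer contributing hours are dropped (and logged).  The
        default requires 18 of 24 hours.
    humidex_from_hourly
        If True (default), hourly humidex values are computed first and then
        averaged; if False, the daily mean humidex is computed from the daily
        mean air temperature and daily mean dew point.

    Returns a frame with :data:`DAILY_COLUMNS`, sorted by date.  Hours whose
    dew point exceeds the air temperature by more than 0.5 degC (sensor
    noise tolerance) are flagged in the log but retained.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations.rename(
            columns={"air_temp_c": "air_temp", "dew_point_c": "dew_point"}
        )[["timestamp", "air_temp", "dew_point"]].copy()
    else:
        rows = [(o.timestamp, o.air_temp, o.dew_point) for o in observations]
        df = pd.DataFrame(rows, columns=["timestamp", "air_temp", "dew_point"])
    if df.empty:
        log.warning("daily_aggregate: no observations supplied")
        return pd.DataFrame(columns=DAILY_COLUMNS)

    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values("timestamp", kind="stable")
    n_suspect = int((df["dew_point"] > df["air_temp"] + 0.5).sum())
    if n_suspect:
        log.warning(
            "daily_aggregate: %d hour(s) with dew point > air temp + 0.5 degC", n_suspect
        )
    df["hourly_humidex"] = compute_humidex(
        df["air_temp"].to_numpy(), df["dew_point"].to_numpy()
    )
    df["date"] = df["timestamp"].dt.date

    grouped = df.groupby("date", sort=True)
    out = grouped.agg(
        mean_air_temp=("air_temp", "mean"),
        mean_dew=("dew_point", "mean"),
        mean_humidex=("hourly_humidex", "mean"),
        max_humidex=("hourly_humidex", "max"),
        n_hours_used=("air_temp", "size"),
    ).reset_index()
    if not humidex_from_hourly:
        out["mean_humidex"] = compute_humidex(
            out["mean_air_temp"].to_numpy(), out["mean_dew"].to_numpy()
        )
    dropped = out["n_hours_used"] < min_hours
    if dropped.any():
        log.info(
            "daily_aggregate: dropping %d day(s) with < %d hours",
            int(dropped.sum()),
            min_hours,
        )
    out = out.loc[~dropped].drop(columns=["mean_dew"]).reset_index(drop=True)
    out["weekday"] = pd.to_datetime(out["date"]).dt.weekday
    return out[DAILY_COLUMNS]


def identify_extreme_days(
    daily: pd.DataFrame, percentile: float, method: str = "linear"
) -> ExtremeDaySet:
    """Find days at/above the given percentile of daily mean air temperature.

    The threshold is the empirical quantile (default: linear interpolation
    between order statistics) of ``mean_air_temp`` over *all* days in the
    series; the set holds every day whose mean air temperature is >= it.
    """
    if daily.empty:
        raise ValueError("identify_extreme_days: empty daily series")
    if not 0.0 < percentile < 1.0:
        raise ValueError(f"identify_extreme_days: percentile {percentile!r} not in (0, 1)")
    temps = daily["mean_air_temp"].to_numpy(dtype=float)
    threshold = float(np.quantile(temps, percentile, method=method))
    mask = temps >= threshold
    dates = frozenset(_as_date(d) for d in daily.loc[mask, "date"])
    return ExtremeDaySet(percentile=percentile, threshold=threshold, dates=dates)


def referent_days(case_date: dt.date, include_case: bool = False) -> list:
    """Time-stratified control days for a case day.

    All dates in the same calendar month and year that share the case date's
    weekday.  The case day itself is excluded by default (the standard
    time-stratified convention); pass ``include_case=True`` for the
    unidirectional variant.  The result is sorted ascending and has 3-4
    members (4-5 with the case day included).
    """
    case_date = _as_date(case_date)
    n_days = calendar.monthrange(case_date.year, case_date.month)[1]
    first_weekday = dt.date(case_date.year, case_date.month, 1).weekday()
    offset = (case_date.weekday() - first_weekday) % 7
    days = range(1 + offset, n_days + 1, 7)
    out = [dt.date(case_date.year, case_date.month, d) for d in days]
    if not include_case:
        out = [d for d in out if d != case_date]
    return out


def stratum_key(d: dt.date) -> tuple:
    """The (year, month, weekday) triple identifying a time stratum."""
    d = _as_date(d)
    return (d.year, d.month, d.weekday())


def read_hourly_csv(path) -> pd.DataFrame:
    """Read an hourly weather CSV: ``timestamp, air_temp_c, dew_point_c``."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "air_temp_c", "dew_point_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hourly weather CSV missing columns: {sorted(missing)}")
    return df


def read_daily_csv(path) -> pd.DataFrame:
    """Read a precomputed daily weather CSV.

    Expected columns: ``date, mean_air_temp_c, mean_humidex_c, max_humidex_c``.
    Returns the canonical daily layout with ``n_hours_used`` set to 24.
    """
    df = pd.read_csv(path)
    required = {"date", "mean_air_temp_c", "mean_humidex_c", "max_humidex_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"daily weather CSV missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "date": pd.to_datetime(df["date"]).dt.date,
            "mean_air_temp": df["mean_air_temp_c"].astype(float),
            "mean_humidex": df["mean_humidex_c"].astype(float),
            "max_humidex": df["max_humidex_c"].astype(float),
            "n_hours_used": df.get("n_hours_used", 24),
        }
    )
    out["weekday"] = pd.to_datetime(out["date"]).dt.weekday
    return out[DAILY_COLUMNS]


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()
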