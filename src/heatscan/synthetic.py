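"""Seeded generator for weather, decedents, and death days.

The confidential inputs of a heat-mortality delineation study — vital
statistics records with residence-level exposure values, and a multi-year
reference-station weather series — cannot be shipped.  This module generates
synthetic stand-ins with the exact statistical structure the analysis
assumes, so every pipeline stage is testable end to end:

* a full-year daily weather series with a seasonal cycle whose July-August
  bulk is Normal(18, 2) degC plus a lightly weighted hot component, so the
  99.9th percentile of daily mean air temperature lands near 24 degC and a
  handful of days exceed it over a 17-year horizon (the structure of greater
  Vancouver summers, where a series of ~6200 days yields ~6 such days);
* decedent-level spatial variables drawn from configurable distributions
  (the default scanned variable is a right-skewed, humidex-map-like shifted
  lognormal whose 70th percentile sits at 34.4 degC);
* death days assigned *within* a time stratum with probability proportional
  to exp(beta_group * H_day) — the conditional-logistic kernel itself — so
  the fitted slopes are consistent for the generating slopes by
  construction, with beta_group determined by whether the decedent's value
  of the scanned variable is at/above the true threshold theta.

Truth (theta and both slopes) is stored separately from the data, and every
output is reproducible bit for bit from (config, seed).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import weather as weather_mod
from .weather import DAILY_COLUMNS, identify_extreme_days, stratum_key

log = logging.getLogger(__name__)

__all__ = [
    "WeatherSpec",
    "SimConfig",
    "SimOutput",
    "default_variable_distributions",
    "distribution_quantile",
    "generate_weather",
    "generate_decedents",
    "paper_scenario",
    "write_csvs",
]

SUMMER_MONTHS = (7, 8)

_ICD_CODES = np.array(["I21", "I25", "I64", "J44", "J18", "C34", "C50", "F03", "E11", "N18"])
_ICD_WEIGHTS = np.array([0.16, 0.14, 0.08, 0.12, 0.08, 0.14, 0.08, 0.08, 0.07, 0.05])


@dataclass(frozen=True)
class WeatherSpec:
    """Parameters of the synthetic reference-station climate (degC)."""

    summer_mean: float = 18.0      # July-August bulk daily mean
    summer_sd: float = 2.0
    hot_weight: float = 0.015      # summer-day probability of the hot component
    hot_mean: float = 23.5
    hot_sd: float = 1.5
    annual_mean: float = 10.5      # annual-cycle midline
    annual_amplitude: float = 7.5  # midline-to-peak seasonal swing
    humidex_offset_mean: float = 1.5  # humidity excess of mean humidex over air temp
    humidex_offset_sd: float = 1.0
    max_offset_mean: float = 5.5   # excess of max humidex over mean humidex
    max_offset_sd: float = 1.5


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated data set.

    ``threshold`` is on the scanned variable's scale; None resolves to that
    variable's distributional 70th percentile.  ``frac_nonqualifying`` sends
    a share of decedents into summer strata without an extreme day, to
    exercise the analytic-set filter.
    """

    seed: int = 0
    n_decedents: int = 997
    years: int = 17
    start_year: int = 1998
    beta_below: float = math.log(1.03)
    beta_above: float = math.log(1.09)
    threshold: float | None = None
    scan_variable: str = "humidex_max_c"
    variable_distribution: dict = field(default_factory=lambda: default_variable_distributions())
    weather_spec: WeatherSpec = field(default_factory=WeatherSpec)
    extreme_percentile: float = 0.999
    p_out_of_hospital: float = 0.258
    frac_nonqualifying: float = 0.0
    copula_corr: float = 0.0  # Gaussian-copula correlation between spatial variables


@dataclass
class SimOutput:
    """Generated weather + decedent tables and the separate truth record."""

    weather: pd.DataFrame
    decedents: pd.DataFrame
    truth: dict
    config: SimConfig


def default_variable_distributions() -> dict:
    """Distribution spec per spatial variable.

    The scanned heat-exposure variable emulates a mapped maximum-humidex
    surface: right-skewed with a long hot tail (coastal bulk, hot inland
    valley), as shifted-lognormal 28 + LogNormal(ln 4, 0.9) degC whose 70th
    percentile is 34.4 degC.  The social variable emulates a census labor
    nonparticipation rate: Normal(37, 14) percent clipped to [0, 100].
    """
    return {
        "humidex_max_c": ("shifted_lognormal", {"shift": 28.0, "mu": math.log(4.0), "sigma": 0.9}),
        "labor_nonparticipation_pct": ("clipped_normal", {"mean": 37.0, "sd": 14.0, "lo": 0.0, "hi": 100.0}),
    }


def distribution_quantile(spec: tuple, q: float) -> float:
    """Analytic quantile of a variable-distribution spec."""
    family, p = spec
    z = norm.ppf(q)
    if family == "shifted_lognormal":
        return p["shift"] + math.exp(p["mu"] + p["sigma"] * z)
    if family == "clipped_normal":
        return float(np.clip(p["mean"] + p["sd"] * z, p["lo"], p["hi"]))
    if family == "normal":
        return p["mean"] + p["sd"] * z
    if family == "uniform":
        return p["lo"] + q * (p["hi"] - p["lo"])
    raise ValueError(f"unknown distribution family {family!r}")


def _draw_from_spec(spec: tuple, z: np.ndarray) -> np.ndarray:
    """Transform standard-normal draws into the spec's distribution."""
    family, p = spec
    if family == "shifted_lognormal":
        return p["shift"] + np.exp(p["mu"] + p["sigma"] * z)
    if family == "clipped_normal":
        return np.clip(p["mean"] + p["sd"] * z, p["lo"], p["hi"])
    if family == "normal":
        return p["mean"] + p["sd"] * z
    if family == "uniform":
        return p["lo"] + norm.cdf(z) * (p["hi"] - p["lo"])
    raise ValueError(f"unknown distribution family {family!r}")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Deterministic sub-stream: one generator per (seed, stream) pair."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_weather(config: SimConfig) -> pd.DataFrame:
    """Full-year daily weather series in the canonical daily-summary layout.

    Daily mean air temperature follows a sinusoidal annual cycle (July peak
    near ``summer_mean``) with Gaussian day-to-day noise; July-August days
    additionally draw, with probability ``hot_weight``, from a hot component
    so the series has a heavy upper tail.  Daily mean humidex is the air
    temperature plus a non-negative humidity offset with noise; the daily
    maximum humidex adds a further positive offset.
    """
    if config.years < 1:
        raise ValueError("generate_weather: years must be >= 1")
    ws = config.weather_spec
    rng = _rng(config, stream=1)
    start = dt.date(config.start_year, 1, 1)
    end = dt.date(config.start_year + config.years - 1, 12, 31)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    # peak on day 197 (mid July); amplitude chosen so July-August ~ summer_mean
    cycle = ws.annual_mean + ws.annual_amplitude * np.cos(
        2.0 * np.pi * (doy - 197.0) / 365.25
    )
    is_summer = np.isin(dates.month, SUMMER_MONTHS)
    cycle[is_summer] = ws.summer_mean
    mean_air = cycle + rng.normal(0.0, ws.summer_sd, size=n)
    hot = is_summer & (rng.random(n) < ws.hot_weight)
    mean_air[hot] = rng.normal(ws.hot_mean, ws.hot_sd, size=int(hot.sum()))
    offset = np.clip(rng.normal(ws.humidex_offset_mean, ws.humidex_offset_sd, size=n), 0.0, None)
    mean_humidex = mean_air + offset
    max_humidex = mean_humidex + np.abs(rng.normal(ws.max_offset_mean, ws.max_offset_sd, size=n))
    out = pd.DataFrame(
        {
            "date": dates.date,
            "weekday": np.asarray(dates.weekday),
            "mean_air_temp": mean_air,
            "mean_humidex": mean_humidex,
            "max_humidex": max_humidex,
            "n_hours_used": 24,
        }
    )
    return out[DAILY_COLUMNS]


def _stratum_table(weather: pd.DataFrame, extreme_dates: frozenset) -> tuple:
    """Qualifying and non-qualifying summer strata with their member days.

    Returns two lists of ``(dates_array, humidex_array)`` tuples, the first
    for strata containing at least one extreme day.
    """
    summer = weather.loc[pd.to_datetime(weather["date"]).dt.month.isin(SUMMER_MONTHS)]
    qualifying, nonqualifying = [], []
    for _, grp in summer.groupby(
        [pd.to_datetime(summer["date"]).dt.year,
         pd.to_datetime(summer["date"]).dt.month,
         summer["weekday"]],
        sort=True,
    ):
        dates = grp["date"].to_numpy()
        hum = grp["mean_humidex"].to_numpy(dtype=float)
        if any(d in extreme_dates for d in dates):
            qualifying.append((dates, hum))
        else:
            nonqualifying.append((dates, hum))
    return qualifying, nonqualifying


def resolve_threshold(config: SimConfig) -> float:
    """The true threshold theta (default: the scan variable's 70th percentile)."""
    if config.threshold is not None:
        return float(config.threshold)
    return float(distribution_quantile(config.variable_distribution[config.scan_variable], 0.70))


def generate_decedents(config: SimConfig, weather: pd.DataFrame) -> SimOutput:
    """Decedent table with death days drawn from the conditional-logistic kernel.

    Per decedent: spatial variables are drawn (optionally Gaussian-copula
    correlated), the true group label is A = 1{scan value >= theta}, a summer
    time stratum is assigned uniformly among strata containing an extreme day
    (a ``frac_nonqualifying`` share goes to strata without one), and the
    death day within the stratum is chosen with probability proportional to
    exp(beta_A * H_day) over the stratum's daily mean humidex values.  This
    is the matched-set likelihood's own kernel, so conditional-logistic
    estimates on the generated data are consistent for (beta_below,
    beta_above) by construction.
    """
    rng = _rng(config, stream=2)
    n = config.n_decedents
    if n < 1:
        raise ValueError("generate_decedents: n_decedents must be >= 1")
    extreme = identify_extreme_days(weather, config.extreme_percentile)
    qualifying, nonqualifying = _stratum_table(weather, extreme.dates)
    if not qualifying:
        raise ValueError("generate_decedents: weather series has no qualifying strata")
    theta = resolve_threshold(config)

    # spatial variables via a Gaussian copula (independent by default)
    names = list(config.variable_distribution)
    k = len(names)
    if config.copula_corr and k > 1:
        corr = np.full((k, k), float(config.copula_corr))
        np.fill_diagonal(corr, 1.0)
        z = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    else:
        z = rng.standard_normal((n, k))
    spatial = {
        name: _draw_from_spec(config.variable_distribution[name], z[:, j])
        for j, name in enumerate(names)
    }
    scan_values = spatial[config.scan_variable]
    group_above = scan_values >= theta

    # stratum assignment
    use_nonqual = (
        (rng.random(n) < config.frac_nonqualifying) if nonqualifying else np.zeros(n, bool)
    )
    idx_qual = rng.integers(0, len(qualifying), size=n)
    idx_nonqual = rng.integers(0, max(len(nonqualifying), 1), size=n)

    betas = np.where(group_above, config.beta_above, config.beta_below)
    death_dates = np.empty(n, dtype=object)
    for i in range(n):
        dates, hum = (
            nonqualifying[idx_nonqual[i]] if use_nonqual[i] else qualifying[idx_qual[i]]
        )
        w = np.exp(betas[i] * (hum - hum.max()))
        death_dates[i] = dates[rng.choice(hum.shape[0], p=w / w.sum())]

    # demographics and administrative fields
    age = np.clip(np.round(rng.normal(75.0, 17.0, size=n)), 0, 110).astype(int)
    sex = np.where(rng.random(n) < 0.49, "M", "F")
    icd10 = rng.choice(_ICD_CODES, size=n, p=_ICD_WEIGHTS / _ICD_WEIGHTS.sum())
    ooh = rng.random(n) < config.p_out_of_hospital
    # out-of-hospital deaths split care-facility : home roughly 160 : 97
    care = rng.random(n) < (160.0 / 257.0)
    place = np.where(ooh, np.where(care, "care_facility", "home"), "hospital")

    decedents = pd.DataFrame(
        {
            "uid": [f"D{i:06d}" for i in range(n)],
            "death_date": death_dates,
            "age": age,
            "sex": sex,
            "icd10": icd10,
            "place_of_death": place,
            **{name: spatial[name] for name in names},
        }
    )
    truth = {
        "theta": theta,
        "beta_below": config.beta_below,
        "beta_above": config.beta_above,
        "or_below": math.exp(config.beta_below),
        "or_above": math.exp(config.beta_above),
        "scan_variable": config.scan_variable,
        "group_above": group_above.tolist(),
        "in_qualifying_stratum": (~use_nonqual).tolist(),
        "extreme_threshold": extreme.threshold,
        "n_extreme_days": len(extreme.dates),
    }
    return SimOutput(weather=weather, decedents=decedents, truth=truth, config=config)


def simulate(config: SimConfig) -> SimOutput:
    """Generate weather and decedents in one call."""
    return generate_decedents(config, generate_weather(config))


def paper_scenario(seed: int = 0, **overrides) -> SimOutput:
    """Preset emulating the published study's headline conditions.

    997 decedents over 17 years with true odds ratios 1.09 (above) and 1.03
    (below) per degC, threshold 34.4 degC on the humidex-like scanned
    variable (its 70th percentile), and a 25.8% out-of-hospital share.
    """
    config = SimConfig(
        seed=seed,
        n_decedents=997,
        years=17,
        beta_above=math.log(1.09),
        beta_below=math.log(1.03),
        threshold=34.4,
        **overrides,
    )
    return simulate(config)


def write_csvs(sim: SimOutput, outdir) -> dict:
    """Write deaths CSV + daily weather CSV in the ingest dialects, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weather_path = outdir / "weather_daily.csv"
    deaths_path = outdir / "deaths.csv"
    truth_path = outdir / "truth.json"
    w = sim.weather.rename(
        columns={
            "mean_air_temp": "mean_air_temp_c",
            "mean_humidex": "mean_humidex_c",
            "max_humidex": "max_humidex_c",
        }
    )[["date", "mean_air_temp_c", "mean_humidex_c", "max_humidex_c", "n_hours_used"]]
    w.to_csv(weather_path, index=False)
    sim.decedents.to_csv(deaths_path, index=False)
    truth = {k: v for k, v in sim.truth.items() if k not in ("group_above", "in_qualifying_stratum")}
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {"weather": weather_path, "deaths": deaths_path, "truth": truth_path}
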