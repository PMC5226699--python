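"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from heatscan import clogit, cohort, delineation, synthetic, weather as weather_mod


def make_daily(dates, mean_air, mean_humidex=None):
    """Minimal daily-summary frame for hand-built fixtures."""
    dates = [pd.Timestamp(d).date() for d in dates]
    mean_air = np.asarray(mean_air, dtype=float)
    hum = mean_air + 2.0 if mean_humidex is None else np.asarray(mean_humidex, float)
    return pd.DataFrame(
        {
            "date": dates,
            "weekday": [d.weekday() for d in dates],
            "mean_air_temp": mean_air,
            "mean_humidex": hum,
            "max_humidex": hum + 5.0,
            "n_hours_used": 24,
        }
    )


def make_records(rows, spatial_cols=()):
    """Deaths frame from (uid, death_date, icd10, place) tuples + spatial values."""
    recs = []
    for row in rows:
        uid, date, icd, place = row[:4]
        rec = {
            "uid": uid,
            "death_date": pd.Timestamp(date).date(),
            "age": 80,
            "sex": "F",
            "icd10": icd,
            "place_of_death": place,
        }
        for name, value in zip(spatial_cols, row[4:]):
            rec[name] = value
        recs.append(rec)
    return pd.DataFrame(recs)


def run_scan_replicate(seed, n_decedents=2000, beta_above=math.log(1.10),
                       beta_below=math.log(1.03), **overrides):
    """Generate one synthetic study and run the full scan on its default variable.

    Returns (sim, stack, grid, results, cut).
    """
    cfg = synthetic.SimConfig(
        seed=seed,
        n_decedents=n_decedents,
        beta_above=beta_above,
        beta_below=beta_below,
        **overrides,
    )
    sim = synthetic.simulate(cfg)
    extreme = weather_mod.identify_extreme_days(sim.weather, cfg.extreme_percentile)
    strata = cohort.build_analytic_dataset(sim.decedents, sim.weather, extreme)
    stack = clogit.stack_strata(strata)
    values = pd.Series(
        sim.decedents[cfg.scan_variable].to_numpy(), index=sim.decedents["uid"]
    )
    grid = delineation.make_split_grid(
        values.loc[list(stack.uids)].to_numpy(), variable=cfg.scan_variable
    )
    results = delineation.scan(stack, values, grid)
    cut = delineation.find_cut_point(results, variable=cfg.scan_variable)
    return sim, stack, grid, results, cut


def simulate_matched_sets(rng, n_strata=50, rows_per_stratum=4, n_covariates=1,
                          beta=None):
    """Random 1:M matched sets drawn from the conditional-logistic model."""
    if beta is None:
        beta = rng.normal(0.0, 0.5, size=n_covariates)
    beta = np.atleast_1d(beta)
    n = n_strata * rows_per_stratum
    groups = np.repeat(np.arange(n_strata), rows_per_stratum)
    X = rng.normal(size=(n, beta.shape[0]))
    y = np.zeros(n, dtype=int)
    for s in range(n_strata):
        sl = slice(s * rows_per_stratum, (s + 1) * rows_per_stratum)
        p = np.exp(X[sl] @ beta)
        y[s * rows_per_stratum + rng.choice(rows_per_stratum, p=p / p.sum())] = 1
    return y, X, groups, beta


@pytest.fixture(scope="session")
def paper_sim():
    """One published-study-preset simulation, shared across tests."""
    return synthetic.paper_scenario(seed=42)


@pytest.fixture(scope="session")
def small_scan():
    """One moderate-size scan replicate shared by delineation tests."""
    return run_scan_replicate(seed=321, n_decedents=800)
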