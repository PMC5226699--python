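"""Decedent records, eligibility filters, and the analytic case-crossover set.

The unit of analysis is the *stratum*: one decedent's case day (death date)
plus its time-stratified control days, each carrying the daily mean humidex
measured at the fixed reference station.  The analytic data set keeps only
strata that touch at least one extremely hot day, either as the case day or
as a control day — deaths on extreme days and deaths on comparable cooler
days that share a stratum with one.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .weather import ExtremeDaySet, referent_days, _as_date

log = logging.getLogger(__name__)

__all__ = [
    "MortalityRecord",
    "Stratum",
    "BASE_COLUMNS",
    "filter_records",
    "invert_protective_variables",
    "build_analytic_dataset",
    "spatial_variable_names",
    "read_deaths_csv",
]

#: non-spatial columns of a deaths table; everything else is a spatial variable
BASE_COLUMNS = ["uid", "death_date", "age", "sex", "icd10", "place_of_death"]

OUT_OF_HOSPITAL_PLACES = {"home", "care_facility", "other"}


@dataclass(frozen=True)
class MortalityRecord:
    """One decedent: identifiers, demographics, and residence-level spatial values."""

    uid: str
    death_date: dt.date
    age: float
    sex: str
    icd10: str
    place_of_death: str
    spatial_values: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Stratum:
    """One decedent's matched set: case day, control days, and exposures.

    ``exposure`` maps every stratum date to the daily mean humidex; the
    outcome is 1 on ``case_date`` and 0 on every control date.
    """

    uid: str
    case_date: dt.date
    control_dates: tuple
    exposure: dict

    @property
    def dates(self) -> list:
        return [self.case_date, *self.control_dates]

    def outcome(self, d: dt.date) -> int:
        return int(d == self.case_date)


def spatial_variable_names(records: pd.DataFrame) -> list:
    """Column names in a deaths table that carry spatial variables."""
    return [c for c in records.columns if c not in BASE_COLUMNS]


def read_deaths_csv(path) -> pd.DataFrame:
    """Read a deaths CSV (base columns + one column per spatial variable)."""
    df = pd.read_csv(path, dtype={"uid": str, "icd10": str, "place_of_death": str})
    missing = set(BASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"deaths CSV missing columns: {sorted(missing)}")
    df["death_date"] = pd.to_datetime(df["death_date"]).dt.date
    if df["uid"].duplicated().any():
        dupes = df.loc[df["uid"].duplicated(), "uid"].head().tolist()
        raise ValueError(f"deaths CSV has duplicate uids, e.g. {dupes}")
    return df


def _icd_root(code: str) -> str:
    return str(code).strip().upper()[:3]


def filter_records(
    records: pd.DataFrame,
    exclude_icd_range: tuple = ("V01", "V99"),
    restriction: str = "all",
) -> pd.DataFrame:
    """Apply eligibility filters to a deaths table.

    Removes records whose three-character ICD-10 root falls in
    ``exclude_icd_range`` (inclusive; default V01-V99, transport accidents).
    Sub-codes inherit the root's fate.  Codes without a leading letter are
    malformed: they are flagged in the log but retained.

    ``restriction='out_of_hospital'`` additionally keeps only deaths at home,
    in a care facility, or at another non-hospital location; records with an
    unknown place of death (e.g. before the field existed) are excluded from
    that subset.
    """
    if restriction not in ("all", "out_of_hospital"):
        raise ValueError(f"unknown restriction {restriction!r}")
    roots = records["icd10"].map(_icd_root)
    malformed = ~roots.str.slice(0, 1).str.isalpha()
    if malformed.any():
        log.warning(
            "filter_records: %d malformed ICD-10 code(s) retained: %s",
            int(malformed.sum()),
            records.loc[malformed, "icd10"].head().tolist(),
        )
    lo, hi = exclude_icd_range
    excluded = (~malformed) & (roots >= lo) & (roots <= hi)
    out = records.loc[~excluded]
    if restriction == "out_of_hospital":
        place = out["place_of_death"].astype(str).str.lower()
        out = out.loc[place.isin(OUT_OF_HOSPITAL_PLACES)]
    return out.reset_index(drop=True)


def invert_protective_variables(
    spatial: pd.DataFrame,
    university_col: str = "pct_university",
    income_col: str = "avg_income",
    owned_col: str = "pct_owned",
    participation_col: str = "labor_participation_pct",
) -> pd.DataFrame:
    """Re-express protective variables so that larger always means more vulnerable.

    Four variables are protective in their raw form and are inverted:

    * percent with a university degree -> ``pct_no_university`` (complement)
    * percent of homes owned -> ``pct_rented`` (complement)
    * labor participation rate -> ``labor_nonparticipation_pct`` (complement)
    * average income -> ``income_ratio_pct``: the minimum average income over
      all areas divided by the area's average income, in percent, so the
      poorest area scores 100.

    Only the columns present are transformed; the originals are dropped.
    """
    out = spatial.copy()
    if income_col in out.columns:
        income = out[income_col].astype(float)
        if (income <= 0).any():
            bad = out.loc[income <= 0].index.tolist()[:5]
            raise ValueError(f"invert_protective_variables: non-positive income at rows {bad}")
        out["income_ratio_pct"] = 100.0 * income.min() / income
        out = out.drop(columns=[income_col])
    complements = {
        university_col: "pct_no_university",
        owned_col: "pct_rented",
        participation_col: "labor_nonparticipation_pct",
    }
    for src, dst in complements.items():
        if src in out.columns:
            out[dst] = 100.0 - out[src].astype(float)
            out = out.drop(columns=[src])
    return out


def build_analytic_dataset(
    records: pd.DataFrame,
    daily: pd.DataFrame,
    extreme: ExtremeDaySet,
    include_case: bool = False,
) -> list:
    """Assemble the analytic set of case-crossover strata.

    A stratum is emitted for a record iff its case day or at least one of its
    time-stratified control days is an extreme day.  Exposure values are the
    daily mean humidex from ``daily``.  Records whose death date has no
    weather coverage are dropped (counted in the log); control days without
    weather are dropped from their stratum.

    Returns strata sorted by uid, so the output is independent of the input
    record ordering.
    """
    humidex_by_date = {
        _as_date(d): float(h)
        for d, h in zip(daily["date"], daily["mean_humidex"])
    }
    strata: list = []
    n_no_weather = 0
    n_nonqualifying = 0
    for row in records.itertuples(index=False):
        case = _as_date(row.death_date)
        if case not in humidex_by_date:
            n_no_weather += 1
            continue
        controls = referent_days(case, include_case=include_case)
        if not (case in extreme or any(c in extreme for c in controls)):
            n_nonqualifying += 1
            continue
        # the case day is always in the choice set via case_date; never duplicate it
        controls = [c for c in controls if c != case]
        kept_controls = tuple(c for c in controls if c in humidex_by_date)
        if len(kept_controls) < len(controls):
            log.warning(
                "build_analytic_dataset: uid %s lost %d control day(s) without weather",
                row.uid,
                len(controls) - len(kept_controls),
            )
        exposure = {d: humidex_by_date[d] for d in (case, *kept_controls)}
        strata.append(
            Stratum(uid=str(row.uid), case_date=case, control_dates=kept_controls, exposure=exposure)
        )
    if n_no_weather:
        log.warning(
            "build_analytic_dataset: dropped %d record(s) outside weather coverage",
            n_no_weather,
        )
    log.info(
        "build_analytic_dataset: %d strata kept, %d record(s) in non-qualifying strata",
        len(strata),
        n_nonqualifying,
    )
    return sorted(strata, key=lambda s: s.uid)
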