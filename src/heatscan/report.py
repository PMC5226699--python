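"""Run orchestration, configuration, group summaries, and reporting.

``run_pipeline`` wires the stages end to end: daily weather (read or
simulated) -> extreme-day identification -> record filtering -> analytic
strata -> per-variable split scan with cut-point search -> optional
composite-index rescan -> Table-style group summaries.  All numerics land in
CSV/JSON before any optional plotting, and the run log accounts for every
record in the deaths file (included, excluded by ICD filter, excluded for
missing weather, excluded for lacking a qualifying stratum, or excluded by
the out-of-hospital restriction).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clogit, cohort, composite as composite_mod, delineation, weather as weather_mod
from .cohort import build_analytic_dataset, filter_records, spatial_variable_names
from .weather import ExtremeDaySet, identify_extreme_days

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "summarize", "run_pipeline", "scan_results_frame"]


@dataclass
class RunConfig:
    """Configuration of one delineation run (loadable from YAML)."""

    deaths_path: str = ""
    weather_path: str = ""
    output_dir: str = "heatscan_output"
    weather_format: str = "daily"  # "daily" | "hourly"
    extreme_percentile: float = 0.999
    restriction: str = "all"  # "all" | "out_of_hospital"
    variables: list = field(default_factory=list)  # empty -> every spatial column
    threshold_sweep: list = field(default_factory=list)  # extra degC thresholds... as percentiles? degC values
    composite_pair: list = field(default_factory=list)  # [heat variable, social variable]
    composite_cuts: list = field(default_factory=list)  # optional fixed cut points for the pair
    separation_persistence: int = 1
    slope_scale: str = "or"
    include_case_day: bool = False
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"RunConfig: unknown keys {sorted(unknown)}")
        cfg = cls(**raw)
        if list(cfg.threshold_sweep) != sorted(cfg.threshold_sweep):
            raise ValueError("RunConfig: threshold_sweep values must be ascending")
        return cfg


def summarize(strata, records: pd.DataFrame, extreme: ExtremeDaySet) -> pd.DataFrame:
    """Group summary of the analytic set, split by case-day type.

    One group holds decedents whose case day was an extremely hot day, the
    other decedents who died on a qualifying cooler day.  Reports counts,
    deaths-per-day mean and range, percent male, and mean (SD) of age and of
    every spatial variable, with a Welch two-sample t-test per numeric
    variable (significance at alpha = 0.05).  Empty groups yield absent
    statistics (NaN) rather than an error.
    """
    by_uid = records.set_index(records["uid"].astype(str))
    rows = []
    for s in strata:
        rows.append((s.uid, s.case_date, s.case_date in extreme))
    assign = pd.DataFrame(rows, columns=["uid", "case_date", "on_extreme_day"])
    merged = assign.merge(by_uid, left_on="uid", right_index=True, suffixes=("", "_rec"))
    numeric_vars = ["age", *spatial_variable_names(records)]

    out_rows = []
    groups = {
        "extreme_day": merged.loc[merged["on_extreme_day"]],
        "cooler_day": merged.loc[~merged["on_extreme_day"]],
    }
    counts = {name: len(g) for name, g in groups.items()}
    out_rows.append({"statistic": "n_deaths", **counts})
    per_day_stats = {}
    n_days = {}
    for name, g in groups.items():
        per_day = g.groupby("case_date").size()
        n_days[name] = int(per_day.shape[0])
        per_day_stats[name] = (
            f"{per_day.mean():.1f} ({per_day.min()}-{per_day.max()})" if len(g) else "NA"
        )
    out_rows.append({"statistic": "n_days", **n_days})
    out_rows.append({"statistic": "deaths_per_day_mean_range", **per_day_stats})
    pct_male = {
        name: (100.0 * (g["sex"] == "M").mean() if len(g) else np.nan)
        for name, g in groups.items()
    }
    out_rows.append({"statistic": "percent_male", **pct_male})

    for var in numeric_vars:
        row = {"statistic": f"mean_sd_{var}"}
        samples = {}
        for name, g in groups.items():
            x = g[var].astype(float).to_numpy()
            samples[name] = x
            row[name] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})" if x.size > 1 else "NA"
        a, b = samples["extreme_day"], samples["cooler_day"]
        if a.size > 1 and b.size > 1:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row["t_stat"], row["p_value"] = float(t), float(p)
            row["significant_0.05"] = bool(p < 0.05)
        else:
            row["t_stat"] = row["p_value"] = np.nan
            row["significant_0.05"] = False
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def scan_results_frame(results) -> pd.DataFrame:
    """Per-variable scan output table (one row per split)."""
    rows = []
    for r in results:
        rows.append(
            {
                "split_value": r.split_value,
                "or_below": r.or_below,
                "ci_below_lo": r.ci_below[0] if r.ci_below else np.nan,
                "ci_below_hi": r.ci_below[1] if r.ci_below else np.nan,
                "or_above": r.or_above,
                "ci_above_lo": r.ci_above[0] if r.ci_above else np.nan,
                "ci_above_hi": r.ci_above[1] if r.ci_above else np.nan,
                "n_above": r.n_above,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


def _plot_scan(results, cut, slope, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = scan_results_frame(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for side, color in (("below", "0.5"), ("above", "tab:blue")):
        ax.plot(frame["split_value"], frame[f"or_{side}"], color=color, label=f"{side} split")
        ax.fill_between(
            frame["split_value"],
            frame[f"ci_{side}_lo"],
            frame[f"ci_{side}_hi"],
            color=color,
            alpha=0.2,
        )
    if cut.cut_value is not None:
        ax.axvline(cut.cut_value, ls="--", color="k", lw=1)
        if slope is not None:
            xs = frame.loc[frame["split_value"] >= cut.cut_value, "split_value"]
            at_cut = frame.loc[frame["split_value"] >= cut.cut_value, "or_above"].iloc[0]
            ax.plot(xs, at_cut + slope * (xs - xs.iloc[0]), color="k", lw=2)
    ax.axhline(1.0, color="0.8", lw=0.8)
    ax.set_xlabel(cut.variable)
    ax.set_ylabel("OR per 1 degC humidex")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _scan_variable(stack, records, var, persistence, slope_scale):
    values = pd.Series(
        records[var].astype(float).to_numpy(), index=records["uid"].astype(str)
    )
    grid = delineation.make_split_grid(
        values.loc[list(stack.uids)].to_numpy(), variable=var
    )
    results = delineation.scan(stack, values, grid)
    cut = delineation.find_cut_point(results, variable=var, persistence=persistence)
    slope = (
        delineation.slope_above_cut(results, cut, scale=slope_scale)
        if cut.mode != "none"
        else None
    )
    cut.slope_above = slope
    return results, cut


def run_pipeline(config: RunConfig, daily: pd.DataFrame | None = None,
                 records: pd.DataFrame | None = None) -> dict:
    """Execute the full delineation pipeline and write its outputs.

    ``daily`` and ``records`` may be passed in-memory (e.g. from the
    synthetic generator); otherwise they are read from the configured paths.
    Returns the run report as a dict (also written to ``report.json``), with
    per-variable scan CSVs, cut-point JSON including the full gap profile,
    the group-summary CSV, and optional plots under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "accounting": {}, "variables": {}}

    if daily is None:
        daily = (
            weather_mod.daily_aggregate(weather_mod.read_hourly_csv(config.weather_path))
            if config.weather_format == "hourly"
            else weather_mod.read_daily_csv(config.weather_path)
        )
    if records is None:
        records = cohort.read_deaths_csv(config.deaths_path)
    n_total = len(records)

    extreme = identify_extreme_days(daily, config.extreme_percentile)
    report["stages"]["weather"] = {
        "n_days": int(len(daily)),
        "extreme_percentile": config.extreme_percentile,
        "extreme_threshold": extreme.threshold,
        "n_extreme_days": len(extreme.dates),
        "extreme_dates": sorted(str(d) for d in extreme.dates),
    }

    filtered = filter_records(records, restriction="all")
    n_icd_excluded = n_total - len(filtered)
    restricted = (
        filter_records(filtered, restriction="out_of_hospital")
        if config.restriction == "out_of_hospital"
        else filtered
    )
    n_restricted_out = len(filtered) - len(restricted)

    strata = build_analytic_dataset(
        restricted, daily, extreme, include_case=config.include_case_day
    )
    weather_dates = set(daily["date"])
    n_no_weather = int(
        (~restricted["death_date"].isin(weather_dates)).sum()
    )
    n_nonqualifying = len(restricted) - n_no_weather - len(strata)
    report["accounting"] = {
        "n_records": n_total,
        "included": len(strata),
        "excluded_by_icd": n_icd_excluded,
        "excluded_by_restriction": n_restricted_out,
        "excluded_no_weather": n_no_weather,
        "excluded_no_qualifying_stratum": n_nonqualifying,
    }
    if not strata:
        report["stages"]["analytic_set"] = {"status": "failed", "reason": "no strata"}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    stack = clogit.stack_strata(strata)

    summary = summarize(strata, restricted, extreme)
    summary.to_csv(outdir / "group_summary.csv", index=False)
    report["stages"]["analytic_set"] = {
        "status": "ok",
        "n_strata": len(strata),
        "n_on_extreme_days": int(sum(s.case_date in extreme for s in strata)),
        "n_on_cooler_days": int(sum(s.case_date not in extreme for s in strata)),
    }

    variables = list(config.variables) or spatial_variable_names(records)
    for var in variables:
        try:
            results, cut = _scan_variable(
                stack, restricted, var, config.separation_persistence, config.slope_scale
            )
        except ValueError as exc:
            log.warning("scan failed for %s: %s", var, exc)
            report["variables"][var] = {"status": "failed", "reason": str(exc)}
            continue
        frame = scan_results_frame(results)
        frame.to_csv(outdir / f"scan_{var}.csv", index=False)
        report["variables"][var] = {
            "status": "ok",
            "mode": cut.mode,
            "cut_value": cut.cut_value,
            "slope_above": cut.slope_above,
            "n_converged_splits": int(frame["converged"].sum()),
            "gap_profile": [None if np.isnan(g) else float(g) for g in cut.gap_profile],
        }
        if cut.cut_index is not None:
            at = results[cut.cut_index]
            report["variables"][var]["or_above_cut"] = at.or_above
            report["variables"][var]["ci_above_cut"] = at.ci_above
            report["variables"][var]["or_below_cut"] = at.or_below
            report["variables"][var]["ci_below_cut"] = at.ci_below
        if config.make_plots:
            _plot_scan(results, cut, cut.slope_above, outdir / f"scan_{var}.png")

    if len(config.composite_pair) == 2:
        heat_var, soc_var = config.composite_pair
        cuts = {}
        for i, var in enumerate((heat_var, soc_var)):
            if len(config.composite_cuts) == 2:
                cuts[var] = float(config.composite_cuts[i])
            else:
                info = report["variables"].get(var, {})
                cuts[var] = info.get("cut_value")
        if all(c is not None for c in cuts.values()):
            uid_index = restricted["uid"].astype(str)
            re_parts = []
            for var in (heat_var, soc_var):
                vals = pd.Series(
                    restricted[var].astype(float).to_numpy(), index=uid_index
                ).loc[list(stack.uids)]
                re_parts.append(
                    composite_mod.percentile_reclassify(vals, cuts[var], variable=var)
                )
            comp = composite_mod.composite_index(*re_parts)
            comp_results, comp_cut = composite_mod.rescan_composite(stack, comp)
            scan_results_frame(comp_results).to_csv(outdir / "scan_composite.csv", index=False)
            report["composite"] = {
                "pair": [heat_var, soc_var],
                "cuts_used": cuts,
                "mode": comp_cut.mode,
                "cut_value": comp_cut.cut_value,
                "slope_above": comp_cut.slope_above,
            }
            if comp_cut.cut_index is not None:
                at = comp_results[comp_cut.cut_index]
                report["composite"]["or_above_cut"] = at.or_above
                report["composite"]["ci_above_cut"] = at.ci_above
                report["composite"]["or_below_cut"] = at.or_below
                report["composite"]["ci_below_cut"] = at.ci_below
            if config.make_plots:
                _plot_scan(comp_results, comp_cut, comp_cut.slope_above, outdir / "scan_composite.png")
        else:
            report["composite"] = {"status": "skipped", "reason": "no cut point for a component"}

    if config.threshold_sweep:
        report["threshold_sweep"] = {}
        temps = daily["mean_air_temp"].to_numpy(dtype=float)
        for t in config.threshold_sweep:
            sweep_extreme = ExtremeDaySet(
                percentile=float((temps < t).mean()),
                threshold=float(t),
                dates=frozenset(
                    weather_mod._as_date(d)
                    for d, temp in zip(daily["date"], temps)
                    if temp >= t
                ),
            )
            sweep_strata = build_analytic_dataset(
                restricted, daily, sweep_extreme, include_case=config.include_case_day
            )
            entry = {
                "n_extreme_days": len(sweep_extreme.dates),
                "n_strata": len(sweep_strata),
                "variables": {},
            }
            if sweep_strata:
                sweep_stack = clogit.stack_strata(sweep_strata)
                for var in variables:
                    try:
                        _, sweep_cut = _scan_variable(
                            sweep_stack,
                            restricted,
                            var,
                            config.separation_persistence,
                            config.slope_scale,
                        )
                        entry["variables"][var] = {
                            "mode": sweep_cut.mode,
                            "cut_value": sweep_cut.cut_value,
                        }
                    except ValueError as exc:
                        entry["variables"][var] = {"mode": "failed", "reason": str(exc)}
            report["threshold_sweep"][f"{t}"] = entry

    cutpoints = {
        var: {k: v for k, v in info.items() if k != "gap_profile"}
        for var, info in report["variables"].items()
    }
    (outdir / "cut_points.json").write_text(json.dumps(cutpoints, indent=2, sort_keys=True))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
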