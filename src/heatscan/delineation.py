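"""Split-scan delineation of areas with elevated heat-mortality risk.

For one spatial variable the procedure is:

1. place 100 candidate splits from the 1st to the 99th percentile of the
   decedent-level values, equally spaced in *value* (not rank);
2. at each split, dichotomise decedents into below (< split) and at/above
   (>= split) groups and fit the conditional-logistic interaction model,
   yielding an odds ratio per 1 degC of daily mean humidex for each group;
3. the cut point is the smallest split at which the two 95% confidence
   intervals separate with the above-split OR larger; if no split fully
   separates, the point of maximum separation (largest CI gap with the
   above-split OR larger) is reported instead;
4. the post-cut trend is summarised by the least-squares slope of the
   above-split OR against split value over splits at/after the cut.

Because the above/below indicator is constant within a decedent's stratum,
the interaction model's conditional likelihood factorises over the two
groups; each split is therefore fitted as two independent single-slope
conditional fits, which is algebraically identical to the joint two-slope
fit and robust to one side being empty.

No multiple-testing correction is applied across the 100 splits (or across
variables): the scan is an exploratory delineation device, and the null
calibration of the uncorrected rule is quantified by simulation instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import clogit
from .clogit import ClogitFit, StratumStack

log = logging.getLogger(__name__)

__all__ = [
    "SplitGrid",
    "SplitResult",
    "CutPointResult",
    "BinResult",
    "make_split_grid",
    "scan",
    "fit_two_slope",
    "find_cut_point",
    "slope_above_cut",
    "binned_scan",
]

N_SPLITS = 100


@dataclass(frozen=True)
class SplitGrid:
    """100 ascending split values spanning the 1st-99th percentile range."""

    variable: str
    values: np.ndarray

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])


@dataclass
class SplitResult:
    """Above/below odds ratios (per 1 degC humidex) at one split value."""

    split_value: float
    or_above: Optional[float]
    ci_above: Optional[tuple]
    or_below: Optional[float]
    ci_below: Optional[tuple]
    n_above: int
    n_below: int
    converged: bool

    @property
    def usable(self) -> bool:
        """Both sides estimable and converged."""
        return self.converged and self.or_above is not None and self.or_below is not None

    def ci_gap(self) -> float:
        """Lower above-split CI bound minus upper below-split CI bound."""
        if not self.usable:
            return float("nan")
        return self.ci_above[0] - self.ci_below[1]


@dataclass
class CutPointResult:
    """Outcome of the cut-point search over a scan's split results."""

    variable: str
    mode: str  # "full_separation" | "max_separation" | "none"
    cut_value: Optional[float]
    cut_index: Optional[int]
    slope_above: Optional[float] = None
    gap_profile: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class BinResult:
    """Odds ratios for decedents inside one rank bin vs all others."""

    bin_index: int
    lo_value: float
    hi_value: float
    n_in: int
    or_in: Optional[float]
    ci_in: Optional[tuple]
    or_out: Optional[float]
    ci_out: Optional[tuple]
    converged: bool
    flagged: bool = False


def make_split_grid(values, variable: str = "", n_splits: int = N_SPLITS) -> SplitGrid:
    """Equally spaced splits between the 1st and 99th percentiles of ``values``.

    Spacing is in value space, so for heavily skewed variables most splits
    land in the sparse tail; that is deliberate.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"make_split_grid: no finite values for {variable or 'variable'}")
    p1, p99 = np.percentile(v, [1.0, 99.0])
    if not p99 > p1:
        raise ValueError(
            f"make_split_grid: degenerate variable {variable or '<unnamed>'} "
            f"(1st and 99th percentiles both {p1!r})"
        )
    return SplitGrid(variable=variable, values=np.linspace(p1, p99, n_splits))


def _fit_side(stack: StratumStack, stratum_mask: np.ndarray, beta0) -> Optional[ClogitFit]:
    """Single-slope conditional fit restricted to the strata in ``stratum_mask``."""
    if not stratum_mask.any():
        return None
    rows = stratum_mask[stack.row_stratum]
    try:
        return clogit.fit(
            stack.y[rows],
            stack.exposure[rows][:, None],
            stack.row_stratum[rows],
            beta0=beta0,
        )
    except ValueError:
        # no informative strata on this side
        return None


def _side_summary(fit_result: Optional[ClogitFit], delta: float):
    if fit_result is None:
        return None, None, False
    if not fit_result.converged:
        return None, None, False
    o, lo, hi = clogit.or_ci(fit_result, 0, delta=delta)
    return o, (lo, hi), True


def scan(
    stack: StratumStack,
    values_by_uid,
    grid: SplitGrid,
    delta: float = 1.0,
) -> list:
    """Fit the above/below interaction model at every split of ``grid``.

    Parameters
    ----------
    stack : flattened analytic strata (see :func:`heatscan.clogit.stack_strata`).
    values_by_uid : mapping or pandas Series giving each decedent's value of
        the scanned spatial variable.
    grid : the split grid for that variable.
    delta : exposure increment for the reported odds ratios (1 degC).

    Decedents with value >= split form the above group.  A side with zero
    decedents, no informative strata, or a non-converged fit is emitted with
    that side's OR set to None and ``converged=False`` for the split; this is
    expected at extreme splits and is not an error.
    """
    v = np.asarray([values_by_uid[u] for u in stack.uids], dtype=float)
    results: list = []
    warm_above = None
    warm_below = None
    for s in grid.values:
        above = v >= s
        n_above = int(above.sum())
        n_below = stack.n_strata - n_above
        fit_a = _fit_side(stack, above, warm_above)
        fit_b = _fit_side(stack, ~above, warm_below)
        if fit_a is not None and fit_a.converged:
            warm_above = fit_a.coefficients
        if fit_b is not None and fit_b.converged:
            warm_below = fit_b.coefficients
        or_a, ci_a, ok_a = _side_summary(fit_a, delta)
        or_b, ci_b, ok_b = _side_summary(fit_b, delta)
        results.append(
            SplitResult(
                split_value=float(s),
                or_above=or_a,
                ci_above=ci_a,
                or_below=or_b,
                ci_below=ci_b,
                n_above=n_above,
                n_below=n_below,
                converged=ok_a and ok_b,
            )
        )
    return results


def fit_two_slope(stack: StratumStack, above_by_stratum: np.ndarray, delta: float = 1.0):
    """Joint two-slope fit: H within the below group and H within the above group.

    Kept as the reference parameterisation of the interaction model; the scan
    uses the factorised per-side fits, which give identical estimates.
    Returns the :class:`~heatscan.clogit.ClogitFit` with coefficient 0 the
    below-group slope and coefficient 1 the above-group slope.
    """
    a_rows = above_by_stratum[stack.row_stratum].astype(float)
    X = np.column_stack(
        [stack.exposure * (1.0 - a_rows), stack.exposure * a_rows]
    )
    return clogit.fit(stack.y, X, stack.row_stratum)


def find_cut_point(
    results: Sequence[SplitResult],
    variable: str = "",
    persistence: int = 1,
) -> CutPointResult:
    """Locate the delineation cut point from ordered split results.

    Full separation: the *smallest* split value whose above-split 95% CI lies
    entirely above the below-split CI (lower above bound > upper below bound)
    with the above-split OR larger.  ``persistence`` > 1 additionally requires
    the separation to hold at that many consecutive usable splits (the
    default, 1, takes the first separation even if the CIs later re-overlap).

    If no split fully separates, the split with the largest CI gap is
    reported as ``max_separation`` provided the above-split OR exceeds the
    below-split OR there; otherwise the mode is ``none``.  Splits with a
    non-converged fit or an empty side are skipped in the search but appear
    as NaN in the gap profile.
    """
    if not any(r.usable for r in results):
        raise ValueError(f"find_cut_point: no usable splits for {variable or '<unnamed>'}")
    gaps = np.array([r.ci_gap() for r in results])
    separated = [
        r.usable and r.ci_gap() > 0 and r.or_above > r.or_below for r in results
    ]
    for i, r in enumerate(results):
        if not separated[i]:
            continue
        if persistence > 1:
            usable_after = [j for j in range(i, len(results)) if results[j].usable]
            window = usable_after[:persistence]
            if len(window) < persistence or not all(separated[j] for j in window):
                continue
        return CutPointResult(
            variable=variable,
            mode="full_separation",
            cut_value=r.split_value,
            cut_index=i,
            gap_profile=gaps,
        )
    best_i, best_gap = None, -np.inf
    for i, r in enumerate(results):
        if r.usable and r.or_above > r.or_below and r.ci_gap() > best_gap:
            best_i, best_gap = i, r.ci_gap()
    if best_i is None:
        return CutPointResult(
            variable=variable, mode="none", cut_value=None, cut_index=None, gap_profile=gaps
        )
    return CutPointResult(
        variable=variable,
        mode="max_separation",
        cut_value=results[best_i].split_value,
        cut_index=best_i,
        gap_profile=gaps,
    )


def slope_above_cut(
    results: Sequence[SplitResult],
    cut: CutPointResult,
    scale: str = "or",
) -> Optional[float]:
    """Least-squares slope of the above-split OR against split value, post-cut.

    Uses every converged split at or after the cut value.  ``scale='log'``
    regresses the log OR instead (the default follows the plotted OR scale).
    Returns None (flagged in the log) with fewer than 3 usable points.
    """
    if cut.mode == "none" or cut.cut_value is None:
        raise ValueError("slope_above_cut: cut point mode is 'none'")
    xs, ys = [], []
    for r in results:
        if r.split_value >= cut.cut_value and r.or_above is not None and r.converged:
            xs.append(r.split_value)
            ys.append(np.log(r.or_above) if scale == "log" else r.or_above)
    if len(xs) < 3:
        log.warning(
            "slope_above_cut: only %d usable split(s) after the cut; slope undefined",
            len(xs),
        )
        return None
    slope, _ = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    return float(slope)


def binned_scan(
    stack: StratumStack,
    values_by_uid,
    bin_fraction: float,
    delta: float = 1.0,
) -> list:
    """Rank-binned variant of the scan: each bin holds ``bin_fraction`` of decedents.

    Decedents are ranked by the spatial variable and partitioned into
    ``round(1 / bin_fraction)`` contiguous rank bins; for each bin the
    interaction model contrasts in-bin decedents against all others.  Bins
    whose in-bin fit is unavailable (no informative strata, non-convergence)
    are emitted flagged.  Small fractions on small analytic sets give thin
    bins and wide, low-power intervals; those are flagged, not suppressed.
    """
    if not 0.0 < bin_fraction <= 0.5:
        raise ValueError(f"binned_scan: bin_fraction {bin_fraction!r} not in (0, 0.5]")
    v = np.asarray([values_by_uid[u] for u in stack.uids], dtype=float)
    n = v.shape[0]
    k = int(round(1.0 / bin_fraction))
    order = np.argsort(v, kind="stable")
    bin_of = np.empty(n, dtype=np.intp)
    bin_of[order] = (np.arange(n) * k) // n
    out: list = []
    for b in range(k):
        inside = bin_of == b
        fit_in = _fit_side(stack, inside, None)
        fit_out = _fit_side(stack, ~inside, None)
        or_i, ci_i, ok_i = _side_summary(fit_in, delta)
        or_o, ci_o, ok_o = _side_summary(fit_out, delta)
        vals = v[inside]
        out.append(
            BinResult(
                bin_index=b,
                lo_value=float(vals.min()) if vals.size else float("nan"),
                hi_value=float(vals.max()) if vals.size else float("nan"),
                n_in=int(inside.sum()),
                or_in=or_i,
                ci_in=ci_i,
                or_out=or_o,
                ci_out=ci_o,
                converged=ok_i and ok_o,
                flagged=not (ok_i and ok_o),
            )
        )
    return out
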