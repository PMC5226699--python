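"""Combined heat-exposure x social-vulnerability index.

Each of the two chosen variables (e.g. mapped maximum humidex and the labor
nonparticipation rate) is reclassified onto a 0-100 percentile scale hinged
at its delineation cut point: values below the cut fill (0, 50] and values
at/above the cut fill (50, 100], with 100 equal-count rank bins per side
(each bin holds 0.5 points of the output scale).  The composite index is the
mean of the two reclassified variables, so 50 marks "at both cut points" and
larger values mark areas that are high on both dimensions.

Percentile binning operates on the statistical unit of this package —
decedent-level values — not on map pixels; a raster adapter is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import delineation
from .clogit import StratumStack

log = logging.getLogger(__name__)

__all__ = [
    "ReclassifiedVariable",
    "percentile_reclassify",
    "composite_index",
    "rescan_composite",
]

_BINS_PER_SIDE = 100  # 0.5-point output bins covering each 50-point half


@dataclass
class ReclassifiedVariable:
    """Per-decedent percentile values in (0, 100], hinged at ``cut_value``."""

    variable: str
    cut_value: float
    percentile_values: pd.Series


def _side_percentiles(raw: np.ndarray) -> np.ndarray:
    """Map one side's raw values to 0.5-point bin values in (0, 50] by average rank."""
    m = raw.shape[0]
    pct = 100.0 * rankdata(raw, method="average") / m  # (0, 100]
    bins = np.clip(np.ceil(pct - 1e-9), 1, _BINS_PER_SIDE)
    return 0.5 * bins


def percentile_reclassify(
    values,
    cut_value: float,
    min_value: float | None = None,
    max_value: float | None = None,
    variable: str = "",
    whole_data_bins: bool = False,
) -> ReclassifiedVariable:
    """Hinged percentile reclassification of decedent-level values.

    Values strictly below ``cut_value`` are ranked within the below-cut
    subset and mapped into (0, 50]; values at/above the cut are ranked within
    the above-cut subset and mapped into (50, 100].  Each side uses 100
    equal-count bins of 0.5 output points, ties sharing their average rank's
    bin.  Both sides must be non-empty.

    ``min_value``/``max_value`` bound the admissible raw range; out-of-range
    values are clamped with a warning.  ``whole_data_bins=True`` switches to
    percentile ranks over the *whole* sample instead of per side (only
    meaningful when the cut sits at the median; per-side is the default
    because it reproduces the 0-50 / 50-100 ranges for any cut position).
    """
    s = pd.Series(values, dtype=float)
    v = s.to_numpy(copy=True)
    if min_value is not None and max_value is not None and min_value > max_value:
        raise ValueError("percentile_reclassify: min_value > max_value")
    for bound, side in ((min_value, "below"), (max_value, "above")):
        if bound is None:
            continue
        out_of_range = v < bound if side == "below" else v > bound
        if out_of_range.any():
            log.warning(
                "percentile_reclassify(%s): clamping %d value(s) %s the %s bound",
                variable or "<unnamed>",
                int(out_of_range.sum()),
                side,
                side,
            )
            v[out_of_range] = bound
    below = v < cut_value
    above = ~below
    if not below.any():
        raise ValueError(
            f"percentile_reclassify({variable or '<unnamed>'}): below-cut side is empty"
        )
    if not above.any():
        raise ValueError(
            f"percentile_reclassify({variable or '<unnamed>'}): above-cut side is empty"
        )
    out = np.empty_like(v)
    if whole_data_bins:
        pct = 100.0 * rankdata(v, method="average") / v.shape[0]
        out = 0.5 * np.clip(np.ceil(2.0 * pct - 1e-9), 1, 2 * _BINS_PER_SIDE)
    else:
        out[below] = _side_percentiles(v[below])
        out[above] = 50.0 + _side_percentiles(v[above])
    return ReclassifiedVariable(
        variable=variable,
        cut_value=float(cut_value),
        percentile_values=pd.Series(out, index=s.index),
    )


def composite_index(temp_re: ReclassifiedVariable, soc_re: ReclassifiedVariable) -> pd.Series:
    """Elementwise mean of two reclassified variables over the same decedents."""
    a, b = temp_re.percentile_values, soc_re.percentile_values
    missing_in_b = a.index.difference(b.index)
    missing_in_a = b.index.difference(a.index)
    if len(missing_in_a) or len(missing_in_b):
        raise ValueError(
            "composite_index: decedent sets differ; "
            f"missing from first: {list(missing_in_a)[:5]}, "
            f"missing from second: {list(missing_in_b)[:5]}"
        )
    return 0.5 * a + 0.5 * b.reindex(a.index)


def rescan_composite(
    stack: StratumStack,
    composite: pd.Series,
    n_splits: int = delineation.N_SPLITS,
    delta: float = 1.0,
) -> tuple:
    """Run the full split-scan delineation on composite-index values.

    ``composite`` must be indexed by uid and cover the analytic set in use
    (which may already be restricted, e.g. to out-of-hospital deaths).
    Returns ``(split_results, cut_point_result)``.
    """
    missing = [u for u in stack.uids if u not in composite.index]
    if missing:
        raise ValueError(f"rescan_composite: no composite value for uids {missing[:5]}")
    grid = delineation.make_split_grid(
        composite.loc[list(stack.uids)].to_numpy(), variable="composite_index", n_splits=n_splits
    )
    results = delineation.scan(stack, composite, grid, delta=delta)
    cut = delineation.find_cut_point(results, variable="composite_index")
    if cut.mode != "none":
        cut.slope_above = delineation.slope_above_cut(results, cut)
    return results, cut
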