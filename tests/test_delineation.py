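"""Split grid, scan, cut-point rule, post-cut slope, and binned variant."""

import math

import numpy as np
import pandas as pd
import pytest

from heatscan import clogit, delineation
from heatscan.delineation import CutPointResult, SplitResult
from conftest import run_scan_replicate


def make_split(value, or_above, ci_above, or_below, ci_below, n_above=50, n_below=50):
    return SplitResult(
        split_value=value,
        or_above=or_above,
        ci_above=ci_above,
        or_below=or_below,
        ci_below=ci_below,
        n_above=n_above,
        n_below=n_below,
        converged=or_above is not None and or_below is not None,
    )


class TestMakeSplitGrid:
    def test_uniform_percentile_oracle(self):
        values = np.arange(0.0, 1001.0)
        grid = delineation.make_split_grid(values, "v")
        p1, p99 = np.percentile(values, [1, 99])
        expected = np.linspace(p1, p99, 100)
        assert np.allclose(grid.values, expected)
        assert grid.values[0] == pytest.approx(10.0)
        assert grid.values[-1] == pytest.approx(990.0)

    def test_construction_properties(self):
        rng = np.random.default_rng(4)
        grid = delineation.make_split_grid(rng.lognormal(0, 1.5, 500), "v")
        assert grid.values.shape == (100,)
        assert np.all(np.diff(grid.values) > 0)
        assert np.allclose(np.diff(grid.values), grid.step)

    def test_skewed_values_stay_equally_spaced_in_value(self):
        # most decedents sit in the bulk; equal spacing puts most splits in the tail
        rng = np.random.default_rng(5)
        v = rng.lognormal(0, 1.5, 2000)
        grid = delineation.make_split_grid(v, "v")
        above_median_splits = (grid.values > np.median(v)).mean()
        assert above_median_splits > 0.8

    def test_degenerate_variable_rejected_by_name(self):
        with pytest.raises(ValueError, match="flatvar"):
            delineation.make_split_grid(np.ones(200), "flatvar")


class TestFindCutPoint:
    def _overlapping(self, n=10):
        return [
            make_split(float(i), 1.05, (0.95, 1.15), 1.02, (0.98, 1.06)) for i in range(n)
        ]

    def test_first_separation_wins(self):
        results = self._overlapping(100)
        for i in range(40, 50):  # separation holds from split 40 onward
            results[i] = make_split(float(i), 1.20, (1.10, 1.30), 1.02, (0.98, 1.06))
        cut = delineation.find_cut_point(results, "v")
        assert cut.mode == "full_separation"
        assert cut.cut_index == 40
        assert cut.cut_value == 40.0

    def test_max_separation_fallback(self):
        results = self._overlapping(20)
        results[7] = make_split(7.0, 1.10, (1.03, 1.18), 1.02, (0.99, 1.05))
        # gap at split 7 is 1.03 - 1.05 = -0.02: still overlapping, but maximal
        cut = delineation.find_cut_point(results, "v")
        assert cut.mode == "max_separation"
        assert cut.cut_index == 7
        assert cut.gap_profile[7] == pytest.approx(-0.02)

    def test_protective_direction_gives_none(self):
        results = [
            make_split(float(i), 0.95, (0.90, 1.00), 1.10, (1.05, 1.15)) for i in range(5)
        ]
        cut = delineation.find_cut_point(results, "v")
        assert cut.mode == "none"
        assert cut.cut_value is None

    def test_nonconverged_splits_skipped_but_profiled(self):
        results = self._overlapping(10)
        results[3] = make_split(3.0, None, None, 1.02, (0.98, 1.06))
        results[5] = make_split(5.0, 1.30, (1.20, 1.40), 1.02, (0.98, 1.06))
        cut = delineation.find_cut_point(results, "v")
        assert cut.cut_index == 5
        assert np.isnan(cut.gap_profile[3])

    def test_persistence_window(self):
        results = self._overlapping(10)
        results[2] = make_split(2.0, 1.30, (1.20, 1.40), 1.02, (0.98, 1.06))  # isolated
        for i in range(6, 10):
            results[i] = make_split(float(i), 1.30, (1.20, 1.40), 1.02, (0.98, 1.06))
        first = delineation.find_cut_point(results, "v")
        assert first.cut_index == 2
        persistent = delineation.find_cut_point(results, "v", persistence=3)
        assert persistent.cut_index == 6

    def test_all_unusable_rejected(self):
        results = [make_split(0.0, None, None, None, None)]
        with pytest.raises(ValueError):
            delineation.find_cut_point(results, "v")


class TestSlopeAboveCut:
    def _cut_at(self, value):
        return CutPointResult(variable="v", mode="full_separation", cut_value=value, cut_index=0)

    def test_flat_or_curve_has_zero_slope(self):
        results = [make_split(float(i), 1.10, (1.05, 1.15), 1.0, (0.9, 1.1)) for i in range(10)]
        assert delineation.slope_above_cut(results, self._cut_at(3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_input(self):
        results = [
            make_split(float(i), 1.0 + 0.01 * (i - 3), (1.0, 1.2), 1.0, (0.9, 1.1))
            for i in range(3, 12)
        ]
        assert delineation.slope_above_cut(results, self._cut_at(3.0)) == pytest.approx(0.01)

    def test_noisy_line_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        xs = np.arange(5.0, 30.0)
        ys = 1.0 + 0.02 * xs + rng.normal(0, 0.01, xs.size)
        results = [
            make_split(x, y, (y - 0.1, y + 0.1), 1.0, (0.9, 1.1)) for x, y in zip(xs, ys)
        ]
        slope = delineation.slope_above_cut(results, self._cut_at(5.0))
        xc = xs - xs.mean()
        oracle = float((xc * (ys - ys.mean())).sum() / (xc**2).sum())
        assert slope == pytest.approx(oracle, abs=1e-10)

    def test_too_few_points_flagged(self):
        results = [make_split(9.0, 1.1, (1.0, 1.2), 1.0, (0.9, 1.1))]
        assert delineation.slope_above_cut(results, self._cut_at(9.0)) is None

    def test_mode_none_rejected(self):
        cut = CutPointResult(variable="v", mode="none", cut_value=None, cut_index=None)
        with pytest.raises(ValueError):
            delineation.slope_above_cut([], cut)


class TestScan:
    def test_factorised_sides_equal_joint_two_slope_fit(self, small_scan):
        sim, stack, grid, results, _ = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        v = values.loc[list(stack.uids)].to_numpy()
        split = grid.values[60]
        above = v >= split
        joint = delineation.fit_two_slope(stack, above)
        r = results[60]
        or_b, lo_b, hi_b = clogit.or_ci(joint, 0)
        or_a, lo_a, hi_a = clogit.or_ci(joint, 1)
        assert r.or_below == pytest.approx(or_b, abs=1e-6)
        assert r.or_above == pytest.approx(or_a, abs=1e-6)
        assert r.ci_above == pytest.approx((lo_a, hi_a), abs=1e-6)
        assert r.ci_below == pytest.approx((lo_b, hi_b), abs=1e-6)

    def test_counts_partition_and_nest(self, small_scan):
        _, stack, _, results, _ = small_scan
        n_above = np.array([r.n_above for r in results])
        assert all(r.n_above + r.n_below == stack.n_strata for r in results)
        assert np.all(np.diff(n_above) <= 0)

    def test_invariant_to_stratum_ordering(self, small_scan):
        sim, stack, grid, results, _ = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(stack.n_strata)
        # rebuild the stack with strata relabelled/permuted
        inv = np.empty_like(perm)
        inv[perm] = np.arange(stack.n_strata)
        order = np.argsort(inv[stack.row_stratum], kind="stable")
        shuffled = clogit.StratumStack(
            uids=stack.uids[perm],
            case_dates=stack.case_dates[perm],
            row_stratum=inv[stack.row_stratum][order],
            y=stack.y[order],
            exposure=stack.exposure[order],
        )
        r2 = delineation.scan(shuffled, values, grid)
        for a, b in zip(results, r2):
            if a.usable and b.usable:
                assert a.or_above == pytest.approx(b.or_above, abs=1e-8)
                assert a.or_below == pytest.approx(b.or_below, abs=1e-8)

    def test_affine_rescaling_transforms_cut_point(self, small_scan):
        sim, stack, grid, results, cut = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        scaled = values * 2.0 + 7.0
        grid2 = delineation.make_split_grid(
            scaled.loc[list(stack.uids)].to_numpy(), variable="v"
        )
        assert np.allclose(grid2.values, grid.values * 2.0 + 7.0)
        r2 = delineation.scan(stack, scaled, grid2)
        cut2 = delineation.find_cut_point(r2, "v")
        assert cut2.mode == cut.mode
        if cut.cut_value is not None:
            assert cut2.cut_value == pytest.approx(cut.cut_value * 2.0 + 7.0, abs=1e-9)

    def test_empty_side_flagged_not_raised(self, small_scan):
        sim, stack, grid, _, _ = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        lone_grid = delineation.SplitGrid(
            variable="v", values=np.array([values.min() - 1.0, values.max() + 1.0])
        )
        res = delineation.scan(stack, values, lone_grid)
        assert res[0].n_below == 0 and res[0].or_below is None
        assert res[0].or_above is not None  # pooled single-slope OR
        assert res[1].n_above == 0 and res[1].or_above is None

    def test_threshold_effect_raises_above_split_curve(self, small_scan):
        # with beta_above > beta_below the above-split OR should trend upward
        # toward the true value as the split approaches theta from below
        sim, _, grid, results, _ = small_scan
        theta = sim.truth["theta"]
        i_theta = int(np.argmin(np.abs(grid.values - theta)))
        early = [r.or_above for r in results[:10] if r.or_above]
        near = [r.or_above for r in results[i_theta - 2 : i_theta + 3] if r.or_above]
        assert np.mean(near) > np.mean(early)


class TestBinnedScan:
    def test_bin_partition_counts(self, small_scan):
        sim, stack, _, _, _ = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        bins = delineation.binned_scan(stack, values, 0.20)
        assert len(bins) == 5
        assert sum(b.n_in for b in bins) == stack.n_strata
        sizes = [b.n_in for b in bins]
        assert max(sizes) - min(sizes) <= 1

    def test_thin_bins_are_small_and_flaggable(self, small_scan):
        sim, stack, _, _, _ = small_scan
        values = pd.Series(
            sim.decedents[sim.config.scan_variable].to_numpy(), index=sim.decedents["uid"]
        )
        bins = delineation.binned_scan(stack, values, 0.02)
        assert len(bins) == 50
        assert all(abs(b.n_in - stack.n_strata / 50) <= 1 for b in bins)

    def test_invalid_fraction_rejected(self, small_scan):
        _, stack, _, _, _ = small_scan
        with pytest.raises(ValueError):
            delineation.binned_scan(stack, {}, 0.75)
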