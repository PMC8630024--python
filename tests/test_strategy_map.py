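"""Strategy classification, region grids, contour extraction and convergence."""

import numpy as np
import pytest

from hostcycle import (
    ProbeSpec,
    SensitivityVector,
    Traits,
    TraitGridSpec,
    baseline_contour,
    classify_strategy,
    extract_contours,
    hausdorff_distance,
    scenario_matrix,
    stage_biased_initial,
    strategy_grid,
)
from hostcycle.strategy_map import UndefinedStrategyError, _stack


def sv(s_rE=0.0, s_rH=0.0, s_mE=0.0, s_mH=0.0):
    return SensitivityVector(s_rE, s_rH, s_mE, s_mH, method="analytic")


def brute_force_contour_m(r_H: float, m_grid: np.ndarray) -> float:
    """Crossing of |s_mH| = |s_rH| via numeric eigenvalues + differences.

    Fully independent of the closed-form gradient: the deciding difference
    is built from central differences of the numerically computed top
    eigenvalue, then the sign change is located along the m axis.
    """
    def eig(r_H, m_E, m_H):
        A = np.array([[r_H - m_E, m_H], [m_E, 1.0 - m_H]])
        return float(np.max(np.linalg.eigvals(A).real))

    h = 1e-6

    def deciding(m):
        s_rH = (eig(r_H + h, m, m) - eig(r_H - h, m, m)) / (2 * h)
        s_mH = (eig(r_H, m, m + h) - eig(r_H, m, m - h)) / (2 * h)
        return abs(s_mH) - abs(s_rH)

    vals = np.array([deciding(m) for m in m_grid])
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(idx) == 0:
        return np.nan
    i = idx[0]
    # linear interpolation across the sign change
    return m_grid[i] + (m_grid[i + 1] - m_grid[i]) * (-vals[i]) / (vals[i + 1] - vals[i])


class TestClassifyStrategy:
    def test_derived_example_prefers_lower_host_influx(self):
        # the analytic gradient at (r_H=0.1, m=0.5): |s_mH| wins
        s = sv(s_rH=0.16552, s_mE=0.20613, s_mH=-0.46284)
        assert classify_strategy(s).roman == "II"

    @pytest.mark.parametrize(
        "vec, roman",
        [
            (sv(s_rH=0.9, s_mE=0.1, s_mH=-0.2), "I"),
            (sv(s_rH=0.1, s_mE=0.5, s_mH=-0.2), "III"),
            (sv(s_rH=0.1, s_mE=0.2, s_mH=0.6), "IV"),
        ],
    )
    def test_catalog(self, vec, roman):
        assert classify_strategy(vec).roman == roman

    def test_excluded_trait_ignored_even_when_largest(self):
        s = sv(s_rE=5.0, s_rH=0.3, s_mE=0.1, s_mH=-0.2)
        assert classify_strategy(s).trait == "r_H"

    def test_exact_tie_is_flagged_and_broken_deterministically(self):
        s = sv(s_rH=0.5, s_mE=0.1, s_mH=-0.5)
        label = classify_strategy(s)
        assert label.boundary
        assert label.trait == "r_H"  # tie-break order r_H, m_H, m_E

    def test_zero_gradient_rejected(self):
        with pytest.raises(UndefinedStrategyError):
            classify_strategy(sv(s_rE=1.0))


class TestStrategyGrid:
    def test_baseline_regions(self, no_competition):
        grid = TraitGridSpec(x_num=21, y_num=20)
        smap = strategy_grid(grid, "analytic", no_competition)
        # high migration, near-parity replication: invest in r_H
        ix = int(np.argmin(np.abs(grid.x_values - 0.9)))
        iy = int(np.argmin(np.abs(grid.y_values - 1.5)))
        assert smap.label_at(ix, iy).roman == "I"
        # slow host, slow migration: cut the influx to the host
        ix = int(np.argmin(np.abs(grid.x_values - 0.1)))
        iy = int(np.argmin(np.abs(grid.y_values - 0.2)))
        assert smap.label_at(ix, iy).roman == "II"

    def test_baseline_map_never_shows_strategy_iv(self, no_competition):
        smap = strategy_grid(TraitGridSpec(x_num=41, y_num=40), "analytic", no_competition)
        romans = {l.roman for l in smap.labels.ravel() if l is not None}
        assert "IV" not in romans
        assert romans == {"I", "II"}

    def test_strategy_iv_emerges_under_fast_compartment_competition(self):
        # crowded environment + tiny migration: escaping into the host wins
        grid = TraitGridSpec(x_num=11, y_num=10, y_range=(0.02, 0.5))
        probe = ProbeSpec(t_max=30, n0=stage_biased_initial("ENVIRONMENT"),
                          rtol=1e-9, atol=1e-12)
        smap = strategy_grid(
            grid, "finite_difference", scenario_matrix("equal_per_compartment", 2.0), probe
        )
        romans = {l.roman for l in smap.labels.ravel() if l is not None}
        assert "IV" in romans

    def test_analytic_method_requires_no_competition(self):
        with pytest.raises(Exception):
            strategy_grid(TraitGridSpec(), "analytic", scenario_matrix("global", 1.0))

    def test_per_point_failures_are_recorded_not_fatal(self):
        # equilibrium method over a grid straddling the existence boundary
        grid = TraitGridSpec(x_num=5, y_num=6, y_range=(0.5, 3.0))
        smap = strategy_grid(grid, "equilibrium", scenario_matrix("host_only", 1.0))
        assert len(smap.errors) > 0  # the m_H < r_E strip has no equilibrium
        labeled = sum(1 for l in smap.labels.ravel() if l is not None)
        assert labeled > 0

    def test_classification_consistent_between_analytic_and_finite_difference(
        self, no_competition
    ):
        # k = 0 at a long horizon: both sensitivity routes label the grid
        # identically away from the region boundary
        grid = TraitGridSpec(x_num=11, y_num=10)
        an = strategy_grid(grid, "analytic", no_competition)
        probe = ProbeSpec(t_max=300)
        fd = strategy_grid(grid, "finite_difference", no_competition, probe)
        decide = an.deciding_difference()
        off_contour = np.abs(decide) > 0.02
        agree = total = 0
        for iy in range(grid.y_num):
            for ix in range(grid.x_num):
                if not off_contour[iy, ix]:
                    continue
                total += 1
                if an.labels[iy, ix].roman == fd.labels[iy, ix].roman:
                    agree += 1
        assert total > 50
        assert agree / total >= 0.99

    def test_to_frame_is_tidy(self, no_competition):
        smap = strategy_grid(TraitGridSpec(x_num=3, y_num=3), "analytic", no_competition)
        df = smap.to_frame()
        assert len(df) == 9
        assert {"r_H", "m", "strategy", "s_rH", "s_mH"} <= set(df.columns)


class TestContours:
    def test_baseline_contour_is_the_line_m_equals_one_minus_rh(self, no_competition):
        grid = TraitGridSpec(x_num=41, y_num=40)
        smap = strategy_grid(grid, "analytic", no_competition)
        pts = _stack(extract_contours(smap))
        assert len(pts) > 10
        step = max(grid.step)
        assert np.max(np.abs(pts[:, 1] - (1.0 - pts[:, 0]))) <= step

    def test_contour_matches_brute_force_scan(self, no_competition):
        # independent oracle: numeric eigenvalues + central differences
        grid = TraitGridSpec(x_num=21, y_num=40)
        smap = strategy_grid(grid, "analytic", no_competition)
        pts = _stack(extract_contours(smap))
        m_fine = np.linspace(0.02, 2.0, 400)
        for r_H in (-0.5, 0.0, 0.5):
            m_oracle = brute_force_contour_m(r_H, m_fine)
            m_extracted = pts[np.argmin(np.abs(pts[:, 0] - r_H)), 1]
            assert m_extracted == pytest.approx(m_oracle, abs=max(grid.step))

    def test_single_region_grid_has_no_contour(self, no_competition):
        # far above the boundary line the whole window is strategy I
        grid = TraitGridSpec(x_num=5, y_num=5, x_range=(0.8, 0.99), y_range=(1.5, 2.0))
        smap = strategy_grid(grid, "analytic", no_competition)
        assert extract_contours(smap) == []

    def test_point_on_baseline_contour(self, no_competition):
        grid = TraitGridSpec(x_num=41, y_num=40)
        pts = baseline_contour(grid)
        d = np.min(np.hypot(pts[:, 0] - 0.5, pts[:, 1] - 0.5))
        assert d <= max(grid.step)


class TestContourConvergence:
    def test_environment_biased_start_collapses_to_baseline(self, mixed_start):
        # equal crowding leaves the compartment split untouched, and the
        # environment-heavy start is already near the stable distribution:
        # no transient, every probing time gives the asymptotic contour
        grid = TraitGridSpec(x_num=21, y_num=20)
        ref = baseline_contour(grid)
        n0 = stage_biased_initial("ENVIRONMENT")
        two_steps = 2 * max(grid.step)
        for t_max in (0.7, 3.0):
            probe = ProbeSpec(t_max=t_max, n0=n0, rtol=1e-9, atol=1e-12)
            smap = strategy_grid(grid, "finite_difference", scenario_matrix("global", 1.0), probe)
            pts = _stack(extract_contours(smap))
            assert hausdorff_distance(pts, ref) <= two_steps

    def test_mixed_start_converges_with_probing_time(self, mixed_start):
        grid = TraitGridSpec(x_num=15, y_num=14)
        ref = baseline_contour(grid)
        dists = []
        for t_max in (0.7, 3.0, 10.0):
            probe = ProbeSpec(t_max=t_max, n0=mixed_start, rtol=1e-9, atol=1e-12)
            smap = strategy_grid(grid, "finite_difference", scenario_matrix("global", 1.0), probe)
            dists.append(hausdorff_distance(_stack(extract_contours(smap)), ref))
        assert dists[0] > dists[1] > dists[2]

    def test_probing_time_and_competition_push_the_same_way(self):
        # host-limited growth: raising either k at fixed t_max or t_max at
        # fixed k drains strategy I out of the no-equilibrium strip m < r_E
        grid = TraitGridSpec(x_num=11, y_num=10, y_range=(0.1, 0.95))
        n0 = stage_biased_initial("ENVIRONMENT")

        def frac_I(k_val, t_max):
            probe = ProbeSpec(t_max=t_max, n0=n0, rtol=1e-9, atol=1e-12)
            smap = strategy_grid(
                grid, "finite_difference", scenario_matrix("host_only", k_val), probe
            )
            labs = [l.roman for l in smap.labels.ravel() if l]
            return sum(1 for r in labs if r == "I") / len(labs)

        baseline_map = strategy_grid(grid, "analytic", scenario_matrix("none"))
        frac_baseline = sum(
            1 for l in baseline_map.labels.ravel() if l and l.roman == "I"
        ) / baseline_map.labels.size

        weak = frac_I(0.02, 2.0)
        assert weak == pytest.approx(frac_baseline, abs=0.05)
        stronger_k = frac_I(0.2, 2.0)
        strongest_k = frac_I(1.0, 2.0)
        longer_t = frac_I(0.02, 8.0)
        assert weak > stronger_k > strongest_k == 0.0
        assert longer_t < weak


class TestTraitGridSpec:
    def test_degenerate_range_rejected(self):
        with pytest.raises(Exception):
            TraitGridSpec(x_range=(1.0, 1.0))

    def test_symmetric_axis_sets_both_migration_rates(self):
        grid = TraitGridSpec()
        tr = grid.traits_at(0.3, 0.7)
        assert tr.m_E == tr.m_H == 0.7
        assert tr.r_H == 0.3
        assert tr.r_E == 1.0
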