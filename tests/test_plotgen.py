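"""Window selection, percentile clipping, histogramming and blank detection."""

import numpy as np
import pytest

import icering as ir
from icering.plotgen import InsufficientDataError, PlotConfig
from icering.reflection_io import ValueKind

from conftest import random_reflection_set


class TestWindowTable:
    def test_default_table_is_the_eight_lettered_windows(self, window_table):
        assert [w.label for w in window_table] == list("ABCDEFGH")
        centres = [(w.d_high + w.d_low) / 2 for w in window_table]
        # hexagonal-ice ring positions, coarse check
        np.testing.assert_allclose(
            centres, [3.88, 3.65, 3.42, 2.67, 2.25, 2.07, 1.95, 1.88], atol=0.02
        )
        for prev, nxt in zip(window_table, window_table[1:]):
            assert prev.d_low > nxt.d_high  # non-overlapping, sorted by 1/d^2

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            ir.IceRingRange("X", d_high=2.0, d_low=3.0)


class TestSelectRanges:
    def test_full_span_selects_all_eight(self, window_table):
        cell = ir.UnitCell(60, 60, 60)
        hkl = [[1, 0, 0], [0, 0, 40]]  # d = 60 and 1.5 A
        rs = ir.ReflectionSet(cell, "intensity", hkl, [1.0, 1.0])
        assert ir.select_ranges(rs, window_table) == window_table

    def test_low_resolution_data_selects_none(self, window_table):
        cell = ir.UnitCell(60, 60, 60)
        rs = ir.ReflectionSet(cell, "intensity", [[1, 0, 0], [0, 0, 7]], [1.0, 1.0])
        assert rs.d_min > 8
        assert ir.select_ranges(rs, window_table) == []

    def test_partially_reached_window_excluded(self):
        window = ir.IceRingRange("X", d_high=3.9, d_low=3.6)
        cell = ir.UnitCell(40, 40, 40)
        rs = ir.ReflectionSet(cell, "intensity", [[1, 0, 0], [0, 0, 10]], [1.0, 1.0])
        assert rs.d_min == pytest.approx(4.0) or rs.d_min > 3.6  # data stop at 4 A
        assert ir.select_ranges(rs, [window]) == []

    def test_empty_set_errors(self, window_table, cubic_cell):
        rs = ir.ReflectionSet(cubic_cell, "intensity", [[1, 0, 0]], [1.0])
        rs.hkl = rs.hkl[:0]
        rs.value = rs.value[:0]
        rs.d = rs.d[:0]
        with pytest.raises(InsufficientDataError):
            ir.select_ranges(rs, window_table)


class TestClipLimits:
    def test_linear_interpolation_convention(self):
        lo, hi = ir.clip_limits(np.arange(1001, dtype=float))
        assert (lo, hi) == (5.0, 950.0)

    def test_constant_input(self):
        lo, hi = ir.clip_limits(np.full(100, 3.14))
        assert lo == hi == 3.14

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            ir.clip_limits(np.arange(5, dtype=float))

    def test_matches_sort_interpolation_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=333)
        lo, hi = ir.clip_limits(v)
        srt = np.sort(v)

        def pctl(q):
            pos = q / 100 * (len(srt) - 1)
            i = int(np.floor(pos))
            frac = pos - i
            return srt[i] * (1 - frac) + srt[min(i + 1, len(srt) - 1)] * frac

        assert lo == pytest.approx(pctl(0.5), rel=1e-12)
        assert hi == pytest.approx(pctl(95.0), rel=1e-12)


def bruteforce_grid(values, s_coord, s_lo, s_hi, lo, hi, ny, nx):
    """Independent O(N*bins) nested-loop binning oracle."""
    if hi <= lo:
        hi = lo + 1.0  # degenerate clip interval: all mass in the bottom row
    y_edges = np.linspace(lo, hi, ny + 1)
    x_edges = np.linspace(s_lo, s_hi, nx + 1)
    grid = np.zeros((ny, nx))
    for v, s in zip(values, s_coord):
        if not (lo <= v <= hi and s_lo <= s <= s_hi):
            continue
        iy = ix = None
        for b in range(ny):
            top_ok = v <= y_edges[b + 1] if b == ny - 1 else v < y_edges[b + 1]
            if y_edges[b] <= v and top_ok:
                iy = b
                break
        for b in range(nx):
            top_ok = s <= x_edges[b + 1] if b == nx - 1 else s < x_edges[b + 1]
            if x_edges[b] <= s and top_ok:
                ix = b
                break
        if iy is not None and ix is not None:
            grid[iy, ix] += 1
    return grid


class TestMakePlot:
    def test_shape_is_config_bins(self, clean_set, window_table):
        plot = ir.make_plot(clean_set, window_table[3])
        assert plot.counts.shape == (80, 80)
        assert plot.grid.shape == (80, 80)

    def test_zero_reflections_gives_blank_zero_grid(self, window_table, cubic_cell):
        rs = ir.ReflectionSet(cubic_cell, "intensity", [[1, 0, 0], [5, 0, 0]], [1.0, 2.0])
        window = ir.IceRingRange("X", d_high=3.9, d_low=3.8)
        plot = ir.make_plot(rs, window)
        assert plot.blank and plot.n_in_range == 0
        assert not plot.counts.any()

    def test_matches_bruteforce_binning_exactly(self, window_table):
        rng = np.random.default_rng(1234)
        cfg = PlotConfig(min_reflections=1)
        for trial in range(30):
            rs = random_reflection_set(rng, n=int(rng.integers(10, 100)))
            window = window_table[int(rng.integers(len(window_table)))]
            plot = ir.make_plot(rs, window, cfg)
            if plot.n_in_range == 0:
                continue
            mask = window.display_contains(rs.d, cfg.x_pad)
            s_lo, s_hi = window.display_interval(cfg.x_pad)
            expected = bruteforce_grid(
                rs.value[mask], 1 / rs.d[mask] ** 2, s_lo, s_hi,
                plot.clip_lo, plot.clip_hi, 80, 80,
            )
            np.testing.assert_array_equal(plot.counts, expected)

    def test_mass_conservation(self, window_table):
        """Sum of raw counts == number of displayed reflections inside clips."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            p = ir.SimulationParams(n_target=3000, seed=int(rng.integers(1 << 30)))
            rs, _ = ir.simulate_reflections(p)
            for window in (window_table[0], window_table[4]):
                plot = ir.make_plot(rs, window)
                mask = window.display_contains(rs.d, PlotConfig().x_pad)
                v = rs.value[mask]
                inside = (v >= plot.clip_lo) & (v <= plot.clip_hi)
                assert plot.counts.sum() == inside.sum()

    def test_deterministic(self, clean_set, window_table):
        a = ir.make_plot(clean_set, window_table[4])
        b = ir.make_plot(clean_set, window_table[4])
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_monotone_x_mapping(self, clean_set, window_table):
        """Larger 1/d^2 never lands in a lower-index x bin."""
        window = window_table[5]
        cfg = PlotConfig()
        plot = ir.make_plot(clean_set, window, cfg)
        mask = window.display_contains(clean_set.d, cfg.x_pad)
        s = np.sort(1 / clean_set.d[mask] ** 2)
        s_lo, s_hi = window.display_interval(cfg.x_pad)
        cols = np.clip(((s - s_lo) / (s_hi - s_lo) * 80).astype(int), 0, 79)
        assert (np.diff(cols) >= 0).all()
        assert plot.n_in_range == mask.sum()

    def test_normalized_grid_in_unit_interval(self, clean_set, window_table):
        plot = ir.make_plot(clean_set, window_table[2])
        assert plot.grid.min() >= 0 and plot.grid.max() == 1.0


class TestBlankDiscriminator:
    def test_all_zero_values_are_blank(self, window_table):
        cell = ir.UnitCell(70, 70, 70)
        p = ir.SimulationParams(cell=cell, blank_ranges=("E",), blank_mode="zero",
                                n_target=15000, seed=8)
        rs, labels = ir.simulate_reflections(p)
        assert labels["E"] == "blank"
        assert ir.is_blank(rs, window_table[4])

    def test_omitted_shell_is_blank(self, window_table):
        p = ir.SimulationParams(blank_ranges=("D",), blank_mode="omit",
                                n_target=15000, seed=9)
        rs, _ = ir.simulate_reflections(p)
        assert ir.is_blank(rs, window_table[3])

    def test_unmodified_set_is_not_blank(self, clean_set, window_table):
        for window in window_table:
            assert not ir.is_blank(clean_set, window)

    def test_sparse_data_does_not_false_alarm(self, window_table):
        p = ir.SimulationParams(n_target=1000, seed=10)
        rs, _ = ir.simulate_reflections(p)
        for window in window_table:
            assert not ir.is_blank(rs, window)


class TestAveragePlots:
    def test_mean_of_identical_plots_is_identity(self, clean_set, window_table):
        plot = ir.make_plot(clean_set, window_table[1])
        avg = ir.average_plots([plot] * 5)
        np.testing.assert_array_equal(avg, plot.grid)

    def test_two_known_grids(self):
        a = ir.IceRingPlot(counts=np.eye(4), kind=ValueKind.INTENSITY)
        b = ir.IceRingPlot(counts=2 * np.ones((4, 4)), kind=ValueKind.INTENSITY)
        np.testing.assert_allclose(ir.average_plots([a, b]), (np.eye(4) + 1) / 2)

    def test_empty_and_mixed_kinds_error(self):
        a = ir.IceRingPlot(counts=np.eye(4), kind=ValueKind.INTENSITY)
        b = ir.IceRingPlot(counts=np.eye(4), kind=ValueKind.AMPLITUDE)
        with pytest.raises(ValueError):
            ir.average_plots([])
        with pytest.raises(ValueError):
            ir.average_plots([a, b])

    def test_contaminated_minus_clean_peaks_in_central_columns(self, window_table):
        """Averaged contaminated plots show the upward central spike."""
        window = window_table[4]
        clean, cont = [], []
        for seed in range(12):
            base = dict(n_target=12000, seed=1000 + seed)
            rs_clean, _ = ir.simulate_reflections(ir.SimulationParams(**base))
            rs_cont, lab = ir.simulate_reflections(
                ir.SimulationParams(
                    contaminated_ranges=(ir.Contamination("E", 6.0, 0.9),), **base
                )
            )
            assert lab["E"] == "contaminated"
            clean.append(ir.make_plot(rs_clean, window))
            cont.append(ir.make_plot(rs_cont, window))
        diff = ir.average_plots(cont) - ir.average_plots(clean)
        # the ring occupies the central third of columns; only the spike
        # deposits mass in the upper half of the grid, so there the
        # difference must peak in the central columns
        upper_profile = diff[40:, :].mean(axis=0)
        assert 27 <= upper_profile.argmax() < 53
        assert upper_profile[27:53].mean() > np.r_[upper_profile[:10], upper_profile[70:]].mean()
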