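"""Density summaries, windowed MAE, and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tailbench.errors import InsufficientReadsError, UnboundedPeakError
from tailbench.evaluation import (
    DensitySummary,
    bootstrap_ci,
    bootstrap_test,
    common_reads,
    density_estimate,
    fwhm_sd,
    maxpeak,
    windowed_mae,
)


class TestDensity:
    def test_degenerate_sample_peaks_at_its_value(self):
        s = density_estimate([42.0] * 25)
        assert s.maxpeak == pytest.approx(42.0)
        assert s.median == 42.0

    def test_fewer_than_ten_reads_rejected(self):
        with pytest.raises(InsufficientReadsError, match="insufficient"):
            density_estimate(list(range(9)))

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        for sample in ([42.0] * 10, rng.normal(60, 10, 500),
                       np.concatenate([rng.normal(8, 3, 300),
                                       rng.normal(60, 5, 700)])):
            s = density_estimate(sample)
            assert abs(np.trapezoid(s.density, s.grid) - 1.0) < 1e-3

    def test_maxpeak_near_true_mode_of_normal(self):
        x = np.random.default_rng(1).normal(50, 5, 5000)
        s = density_estimate(x)
        assert s.maxpeak == pytest.approx(50.0, abs=1.0)

    def test_maxpeak_resists_contamination_that_biases_the_median(self):
        """In a 70/30 mixture of true-length and short-tail reads the
        density mode stays at the main component while the median slides
        toward the contaminant."""
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(60, 5, 700), rng.normal(8, 3, 300)])
        s = density_estimate(x)
        # independent oracle: brute-force scan of the mixture density
        grid = np.linspace(0, 80, 8001)
        mix = 0.7 * norm.pdf(grid, 60, 5) + 0.3 * norm.pdf(grid, 8, 3)
        assert abs(grid[mix.argmax()] - 60.0) < 0.01
        assert 55 <= s.maxpeak <= 65
        assert s.median < s.maxpeak
        assert maxpeak(s) == s.maxpeak

    def test_symmetric_sample_maxpeak_close_to_median(self):
        x = np.random.default_rng(3).normal(40, 6, 2000)
        s = density_estimate(x)
        assert abs(s.maxpeak - s.median) <= s.bandwidth


class TestFwhm:
    def test_analytic_normal_density_recovers_sigma(self):
        g = np.linspace(30, 90, 513)
        s = DensitySummary(g, norm.pdf(g, 60, 5), 1.0, 1, 60.0, 60.0,
                           float("nan"))
        assert fwhm_sd(s) == pytest.approx(5.0, abs=0.05)

    def test_sampled_normal_matches_sample_sd(self):
        x = np.random.default_rng(4).normal(60, 10, 10_000)
        s = density_estimate(x)
        assert s.fwhm_sd == pytest.approx(10.0, abs=1.0)

    def test_minor_distant_mode_is_ignored(self):
        g = np.linspace(0, 100, 2001)
        d = 0.8 * norm.pdf(g, 70, 4) + 0.2 * norm.pdf(g, 10, 2)
        s = DensitySummary(g, d, 1.0, 1, 70.0, 70.0, float("nan"))
        assert fwhm_sd(s) == pytest.approx(4.0, abs=0.1)

    def test_unbounded_peak_raises(self):
        g = np.linspace(0, 1, 513)
        s = DensitySummary(g, np.full(513, 3.0), 1.0, 1, 0.0, 0.5,
                           float("nan"))
        with pytest.raises(UnboundedPeakError, match="unbounded"):
            fwhm_sd(s)


class TestWindowedMae:
    def test_hand_computed_examples(self):
        assert windowed_mae([28, 32, 20, 40], 30, 2).mae == 0.0
        assert windowed_mae([32, 32, 40, 40], 30, 1).mae == 6.0

    def test_perfect_estimates_have_zero_mae(self):
        for n in (1, 2, 5):
            assert windowed_mae([30.0] * 10, 30, n).mae == 0.0

    def test_incomplete_trailing_window_dropped(self):
        r = windowed_mae([10, 10, 10, 99], 10, 3)
        assert r.n_windows == 1
        assert r.mae == 0.0

    def test_no_complete_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            windowed_mae([1, 2, 3], 10, 5)

    def test_maxpeak_statistic_requires_ten_reads_per_window(self):
        with pytest.raises(ValueError, match="window_n >= 10"):
            windowed_mae(list(range(20)), 10, 5, statistic="maxpeak")


class TestBootstrap:
    def test_perfect_estimates_give_degenerate_ci(self):
        r = bootstrap_ci([60.0] * 30, 60, 10, seed=0)
        assert (r.mae, r.ci_low, r.ci_high) == (0.0, 0.0, 0.0)

    def test_fixed_seed_reproduces_ci_bitwise(self):
        x = np.random.default_rng(5).normal(60, 10, 100)
        a = bootstrap_ci(x, 60, 10, seed=11)
        b = bootstrap_ci(x, 60, 10, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_point_estimate(self):
        x = np.random.default_rng(6).normal(60, 10, 100)
        r = bootstrap_ci(x, 60, 10, seed=1)
        assert r.ci_low <= r.mae <= r.ci_high

    def test_ci_covers_generating_process_mae(self):
        """The 95% CI contains the long-run MAE of the generating process
        in nearly all of 100 replicate simulations."""
        rng = np.random.default_rng(8)
        # long-run MAE of the window-10 median of N(60,10) around 60
        sim = np.median(rng.normal(60, 10, (200_000, 10)), axis=1)
        true_mae = np.abs(sim - 60).mean()
        hits = 0
        for rep in range(100):
            x = rng.normal(60, 10, 100)
            r = bootstrap_ci(x, 60, 10, B=1000, seed=rep)
            hits += r.ci_low <= true_mae <= r.ci_high
        assert hits >= 90

    def test_smallest_nonzero_p_is_one_over_B(self):
        rng = np.random.default_rng(9)
        a = rng.normal(60, 0.1, 50)
        b = rng.normal(100, 0.1, 50)
        t = bootstrap_test(a, b, 60, 10, B=1000, seed=2)
        assert t.p_value == 0.001
        assert t.floored

    def test_identical_groups_have_zero_observed_difference(self):
        x = np.random.default_rng(10).normal(60, 5, 50)
        t = bootstrap_test(x, x.copy(), 60, 10, seed=3)
        assert t.observed_diff == 0.0

    def test_large_spread_difference_is_significant(self):
        rng = np.random.default_rng(12)
        a = rng.normal(60, 3, 500)
        b = rng.normal(60, 30, 500)
        t = bootstrap_test(a, b, 60, 10, B=1000, seed=4)
        assert t.p_value <= 0.01


class TestCommonReads:
    @staticmethod
    def _table(ids, qc="pass"):
        return pd.DataFrame({"read_id": ids, "qc": [qc] * len(ids),
                             "tail_nt": [60.0] * len(ids)})

    def test_all_pass_keeps_everything(self):
        t = {"a": self._table(["r1", "r2"]), "b": self._table(["r1", "r2"])}
        res = common_reads(t)
        assert res.read_ids == {"r1", "r2"}
        assert not res.empty_intersection

    def test_one_tool_failing_all_reads_empties_intersection(self):
        t = {"a": self._table(["r1", "r2"]),
             "b": self._table(["r1", "r2"], qc="no_tail")}
        res = common_reads(t)
        assert res.empty_intersection
        assert all(len(df) == 0 for df in res.tables.values())

    def test_nested_drops_give_min_detection_count(self):
        ids = [f"r{i}" for i in range(20)]
        tables = {"hmm": self._table(ids),
                  "window": self._table(ids[:15]),
                  "anchor": self._table(ids[:8])}
        res = common_reads(tables)
        assert len(res.read_ids) == min(res.detection_counts.values()) == 8


class TestHeadlineProperties:
    def test_maxpeak_beats_median_under_contamination(self):
        """With >=30% short-tail contamination the windowed maxpeak has a
        lower MAE than the windowed median (window 100)."""
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(20):
            est = np.concatenate([rng.normal(60, 8, 350),
                                  rng.normal(8, 3, 150)])
            rng.shuffle(est)
            m_peak = windowed_mae(est, 60, 100, "maxpeak").mae
            m_med = windowed_mae(est, 60, 100, "median").mae
            wins += m_peak < m_med
        assert wins >= 19

    def test_mae_improves_with_window_size(self):
        rng = np.random.default_rng(14)
        better = 0
        for _ in range(20):
            est = np.concatenate([rng.normal(60, 8, 350),
                                  rng.normal(8, 3, 150)])
            rng.shuffle(est)
            m10 = windowed_mae(est, 60, 10, "median").mae
            m100 = windowed_mae(est, 60, 100, "median").mae
            better += m100 <= m10
        assert better >= 19

    def test_peak_width_grows_with_tail_length(self):
        """Multiplicative rate error makes the main-peak SD grow with the
        known length (constant per-sample boundary noise)."""
        rng = np.random.default_rng(15)
        widths = []
        for L in (10, 30, 60, 100, 150):
            est = L * (1 + rng.normal(0, 0.03, 2000)) \
                + rng.normal(0, 60, 2000) / 43.0
            widths.append(density_estimate(est).fwhm_sd)
        assert all(a < b for a, b in zip(widths, widths[1:]))
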