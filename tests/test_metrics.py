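"""Storage metrics: cycle windows, loading suitability, order parameter,
erase statistics, beat analytics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavemem.metrics import (
    MetricParams,
    adp_window,
    alpha_band_for_interference,
    assign_cycles,
    best_gamma,
    erase_statistics,
    item_module_counts,
    loading_suitability,
    o_asyn,
    o_syn,
    order_parameter,
    tau_min,
)
from wavemem.network import DriveComponent, DriveSpec
from wavemem.neuron_if import IFParams
from conftest import make_raster


def theta_windows(psi=0.0, t_stop=500.0, n_modules=1):
    drive = DriveSpec.theta(f_hz=8.0, psi_osc=psi)
    return assign_cycles(drive, 0.0, t_stop, n_modules)


class TestAssignCycles:
    def test_first_peak_and_window(self):
        w = theta_windows()
        assert w.peaks[0][0] == pytest.approx(31.25)
        lo, hi = w.window(0, 0)
        assert (lo, hi) == (pytest.approx(-31.25), pytest.approx(93.75))
        assert w.period == pytest.approx(125.0)

    def test_windows_partition_interval(self):
        w = theta_windows(t_stop=1000.0)
        for z in range(w.n_cycles() - 1):
            assert w.window(0, z)[1] == pytest.approx(w.window(0, z + 1)[0])

    def test_module_windows_delayed_by_gradient(self):
        w = theta_windows(psi=0.9, n_modules=3)
        shift = 0.9 / (2 * math.pi * 8.0) * 1000.0
        assert w.peaks[1][0] - w.peaks[0][0] == pytest.approx(shift)
        assert w.peaks[2][0] - w.peaks[0][0] == pytest.approx(2 * shift)

    def test_boundary_spike_goes_to_later_window(self):
        # spike exactly at a window boundary (93.75) belongs to cycle 1
        item = np.array(["A"], dtype=object)
        raster = make_raster([(93.75, 0)], 1, [0], item=item)
        w = theta_windows()
        c0 = item_module_counts(raster, w, 0, ["A"])
        c1 = item_module_counts(raster, w, 1, ["A"])
        assert c0[0, 0] == 0 and c1[0, 0] == 1

    def test_requires_a_component(self):
        with pytest.raises(ValueError):
            assign_cycles(DriveSpec(components=()), 0.0, 100.0, 1)


class TestLoadingSuitability:
    def test_unopposed_winners(self):
        counts = np.diag([10, 10, 10, 10])
        assert loading_suitability(counts, g=2.0) == 1

    def test_runner_up_within_factor_g_fails(self):
        counts = np.diag([10, 10])
        counts[0, 1] = 6  # winner not at least twice the runner-up
        assert loading_suitability(counts, g=2.0) == 0

    def test_ties_fail_strict_dominance(self):
        assert loading_suitability(np.full((3, 3), 5), g=2.0) == 0

    def test_empty_counts_fail(self):
        assert loading_suitability(np.zeros((4, 4)), g=2.0) == 0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            loading_suitability(np.zeros((3, 4)))

    def test_level_must_exceed_one(self):
        with pytest.raises(ValueError):
            loading_suitability(np.eye(2), g=1.0)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_monotonicity(self, diag, off, bump):
        """Raising a diagonal count never breaks suitability; raising an
        off-diagonal count never creates it."""
        counts = np.full((3, 3), off)
        np.fill_diagonal(counts, diag)
        base = loading_suitability(counts, g=2.0)
        up = counts.copy()
        up[1, 1] += bump
        assert loading_suitability(up, g=2.0) >= base
        down = counts.copy()
        down[0, 2] += bump
        assert loading_suitability(down, g=2.0) <= base


class TestBestGamma:
    def test_single_suitable_frequency(self):
        assert best_gamma({40.0: 0, 50.0: 1, 60.0: 0}) == 50.0

    def test_mean_of_suitable_set(self):
        assert best_gamma({40.0: 1, 50.0: 1, 60.0: 1, 70.0: 0}) == pytest.approx(50.0)

    def test_none_when_no_frequency_suitable(self):
        assert best_gamma({f: 0 for f in (40.0, 50.0)}) is None


def four_item_raster(times_by_item, n_per_item=5):
    """Items A..D in modules 0..3, given first-spike times per member."""
    n = 4 * n_per_item
    module = np.repeat(np.arange(4), n_per_item)
    item = np.array([lab for lab in "ABCD" for _ in range(n_per_item)], dtype=object)
    events = []
    for p, lab in enumerate("ABCD"):
        for j, t in enumerate(times_by_item[lab]):
            events.append((t, p * n_per_item + j))
    return make_raster(events, n, module, item=item)


class TestOrderParameter:
    def test_perfect_synchrony_gives_one(self):
        raster = four_item_raster({lab: [31.25] * 5 for lab in "ABCD"})
        w = theta_windows(n_modules=4)
        assert o_syn(raster, w, 0, "A", 0) == pytest.approx(1.0)

    def test_spread_of_half_delta_t_kills_synchrony(self):
        # population SD = delta_t / 2 = 10 ms -> bracket vanishes no
        # matter the participation
        raster = four_item_raster({"A": [21.25, 41.25, 21.25, 41.25],
                                   **{lab: [31.25] * 5 for lab in "BCD"}})
        w = theta_windows(n_modules=4)
        assert o_syn(raster, w, 0, "A", 0) == pytest.approx(0.0)

    def test_partial_participation_scales_synchrony(self):
        # 4 of 8 neurons fire with sigma = 5 ms: (1/2) * (1 - 2*5/20) = 0.25
        raster = four_item_raster(
            {"A": [26.25, 36.25, 26.25, 36.25],
             **{lab: [31.25] * 8 for lab in "BCD"}}, n_per_item=8)
        w = theta_windows(n_modules=4)
        assert o_syn(raster, w, 0, "A", 0) == pytest.approx(0.25)

    def test_asynchrony_zero_for_identical_means(self):
        raster = four_item_raster({lab: [31.25] * 5 for lab in "ABCD"})
        w = theta_windows(n_modules=4)
        assert o_asyn(raster, w, 0, "A", 0, "B", 1) == 0.0

    def test_asynchrony_saturates_at_delta_t(self):
        raster = four_item_raster({"A": [10.0] * 5, "B": [35.0] * 5,
                                   "C": [31.25] * 5, "D": [31.25] * 5})
        w = theta_windows(n_modules=4)
        assert o_asyn(raster, w, 0, "A", 0, "B", 1) == 1.0

    def test_asynchrony_linear_branch(self):
        raster = four_item_raster({"A": [30.0] * 5, "B": [40.0] * 5,
                                   "C": [31.25] * 5, "D": [31.25] * 5})
        w = theta_windows(n_modules=4)
        assert o_asyn(raster, w, 0, "A", 0, "B", 1) == pytest.approx(0.5)

    def test_empty_item_contributes_zero(self):
        raster = four_item_raster({"A": [31.25] * 5, "B": [], "C": [31.25] * 5,
                                   "D": [31.25] * 5})
        w = theta_windows(n_modules=4)
        assert o_asyn(raster, w, 0, "A", 0, "B", 1) == 0.0

    def test_perfect_storage_reaches_one(self):
        # items separated by >= delta_t, each fully synchronous
        raster = four_item_raster({"A": [5.0] * 5, "B": [30.0] * 5,
                                   "C": [55.0] * 5, "D": [80.0] * 5})
        w = theta_windows(n_modules=4)
        assert order_parameter(raster, w, 0, list("ABCD")) == pytest.approx(1.0)

    def test_fully_synchronized_items_score_zero(self):
        raster = four_item_raster({lab: [31.25] * 5 for lab in "ABCD"})
        w = theta_windows(n_modules=4)
        assert order_parameter(raster, w, 0, list("ABCD")) == pytest.approx(0.0)

    def test_needs_at_least_two_items(self):
        raster = four_item_raster({lab: [31.25] * 5 for lab in "ABCD"})
        w = theta_windows(n_modules=4)
        with pytest.raises(ValueError):
            order_parameter(raster, w, 0, ["A"])

    def test_matches_independent_reference_implementation(self):
        """Hand-built raster with irregular times: the implementation must
        agree with a from-scratch spreadsheet-style evaluation to 1e-12."""
        times = {"A": [28.0, 30.5, 31.0, 33.5, 29.0],
                 "B": [47.0, 48.5, 50.0, 46.0],
                 "C": [66.0, 67.0, 65.5, 68.0, 66.5],
                 "D": [88.0, 84.0, 86.0]}
        raster = four_item_raster({lab: times[lab] + [] for lab in "ABCD"})
        w = theta_windows(n_modules=4)
        params = MetricParams()

        # independent reference: explicit formulas, no shared code path
        def ref_syn(lab):
            ts = np.array(times[lab])
            frac = len(ts) / 5.0
            sigma = np.sqrt(np.mean((ts - ts.mean()) ** 2))
            return frac * max(0.0, 1.0 - (2 * sigma / 20.0) ** 1.0)

        def ref_asyn(a, b):
            sep = abs(np.mean(times[a]) - np.mean(times[b])) / 20.0
            return 0.0 if sep == 0 else min(sep, 1.0)

        syn_avg = np.mean([ref_syn(lab) for lab in "ABCD"])
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
                 ("C", "D")]
        asyn_avg = np.mean([ref_asyn(a, b) for a, b in pairs])
        expected = syn_avg * asyn_avg

        got = order_parameter(raster, w, 0, list("ABCD"), params=params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_components_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = {lab: list(rng.uniform(0.0, 93.0, rng.integers(0, 6)))
                     for lab in "ABCD"}
            raster = four_item_raster(times)
            w = theta_windows(n_modules=4)
            val = order_parameter(raster, w, 0, list("ABCD"))
            assert 0.0 <= val <= 1.0

    def test_synchrony_strictly_decreasing_in_sigma(self):
        w = theta_windows(n_modules=4)
        vals = []
        for sigma in (1.0, 3.0, 5.0, 7.0, 9.0):
            raster = four_item_raster(
                {"A": [31.25 - sigma, 31.25 + sigma],
                 **{lab: [31.25] * 2 for lab in "BCD"}}, n_per_item=2)
            vals.append(o_syn(raster, w, 0, "A", 0))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestEraseStatistics:
    def test_binarization_threshold(self):
        df = pd.DataFrame({"mean_os": [0.3, 0.7, 0.49, 0.51],
                           "f_alpha": [10.0, 10.0, 11.0, 11.0]})
        out, _ = erase_statistics(df, covariates=("f_alpha",))
        assert list(out.p_erase) == [1, 0, 1, 0]

    def test_logistic_parameter_recovery(self):
        rng = np.random.default_rng(123)
        b0, b1 = -20.0, 2.0
        x = rng.uniform(8.0, 13.0, 500)
        p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
        y = rng.uniform(size=500) < p
        df = pd.DataFrame({"f_alpha": x, "mean_os": np.where(y, 0.2, 0.8)})
        _, fits = erase_statistics(df, covariates=("f_alpha",))
        fit = fits["f_alpha"]
        assert not fit.saturated
        assert abs(fit.slope - b1) < 2 * fit.slope_se

    def test_degenerate_outcomes_reported_saturated(self):
        df = pd.DataFrame({"mean_os": [0.8, 0.9, 0.7], "f_alpha": [8.0, 9.0, 10.0]})
        with pytest.warns(UserWarning, match="saturated"):
            _, fits = erase_statistics(df, covariates=("f_alpha",))
        assert fits["f_alpha"].saturated
        assert np.all(fits["f_alpha"].predict([8.0, 13.0]) < 0.05)


class TestBeatAnalytics:
    @pytest.mark.parametrize("fa, ft, expected", [
        (10.0, 8.0, 0.25),
        (12.0, 8.0, 0.125),
    ])
    def test_tau_min_values(self, fa, ft, expected):
        assert tau_min(fa, ft) == expected

    def test_tau_min_symmetric(self):
        assert tau_min(11.0, 8.0) == tau_min(8.0, 11.0)

    def test_equal_frequencies_undefined(self):
        with pytest.raises(ValueError):
            tau_min(8.0, 8.0)

    def test_tau_min_matches_envelope_minimum(self):
        """For 20 random frequency pairs the analytic tau_min lands on the
        numerically located minimum of the two-sine envelope within one
        sampling step."""
        rng = np.random.default_rng(7)
        dt = 0.01  # ms
        for _ in range(20):
            ft = float(rng.uniform(4.0, 8.0))
            fa = float(rng.uniform(ft + 0.5, 13.0))
            beat_period = 1000.0 / (fa - ft)
            t = np.arange(0.0, beat_period, dt)
            env = np.abs(np.cos(math.pi * (fa - ft) * t / 1000.0))
            t_min = t[np.argmin(env)]
            assert t_min == pytest.approx(tau_min(fa, ft) * 1000.0, abs=dt)

    def test_adp_window_boundaries_solve_level_equation(self):
        lo, hi = adp_window(0.85)
        p = IFParams()
        for edge in (lo, hi):
            x = edge / p.tau_adp
            assert x * math.exp(1 - x) == pytest.approx(0.85, abs=1e-9)
        assert lo < p.tau_adp < hi
        assert lo == pytest.approx(74.6, abs=0.1)
        assert hi == pytest.approx(236.0, abs=0.5)

    def test_adp_window_collapses_as_level_approaches_one(self):
        lo, hi = adp_window(0.999999)
        assert hi - lo < 2.0
        assert (lo + hi) / 2 == pytest.approx(140.0, abs=1.0)

    def test_alpha_band_first_minimum(self):
        f_min, f_max, f_mean = alpha_band_for_interference(8.0, level=0.85)
        # root-finding oracle: window [74.6, 236.0] ms maps to
        # 8 + 500/236 .. 8 + 500/74.6 Hz
        assert f_min == pytest.approx(8.0 + 500.0 / 236.03, abs=0.02)
        assert f_max == pytest.approx(8.0 + 500.0 / 74.62, abs=0.02)
        assert f_mean == pytest.approx((f_min + f_max) / 2)

    def test_alpha_band_collapses_with_level(self):
        f_min, f_max, f_mean = alpha_band_for_interference(8.0, level=0.999999)
        assert f_max - f_min < 0.2
        assert f_mean == pytest.approx(8.0 + 500.0 / 140.0, abs=0.1)

    def test_alpha_band_higher_minima_nest_above_theta(self):
        k1 = alpha_band_for_interference(8.0, level=0.85, beat_minimum_index=1)
        k2 = alpha_band_for_interference(8.0, level=0.85, beat_minimum_index=2)
        assert k2[0] > k1[0] and k2[1] > k1[1]

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            adp_window(1.5)
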