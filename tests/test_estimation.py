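import math

import numpy as np
import pytest

import deadtime as dt


def forward_triple(tau, rt1, rt2):
    """Exact paralyzable rates for two sources apart and together."""
    r1 = rt1 * math.exp(-rt1 * tau)
    r2 = rt2 * math.exp(-rt2 * tau)
    s = rt1 + rt2
    return r1, r2, s * math.exp(-s * tau)


def make_measurement(counts, duration=60.0, sources=("s1",), window="OW"):
    return dt.CountMeasurement(
        detector_id="det1",
        window=window,
        t_start=0.0,
        duration=duration,
        counts=counts,
        source_ids=frozenset(sources),
    )


class TestRates:
    def test_net_rate_subtracts_background(self):
        m = make_measurement(6000)
        assert dt.net_rate(m, 2.0) == pytest.approx(98.0)
        assert dt.net_rate(m, 0.0) == pytest.approx(100.0)

    def test_net_rate_floors_at_zero_with_warning(self):
        m = make_measurement(30)  # 0.5 cps
        with pytest.warns(dt.LowCountWarning):
            assert dt.net_rate(m, 2.0) == 0.0

    def test_background_rate_pools_frames(self):
        frames = [
            dt.CountMeasurement("det1", "OW", 0.0, 300.0, 600),
            dt.CountMeasurement("det1", "OW", 5000.0, 300.0, 660),
        ]
        series = dt.MeasurementSeries(frames, [])
        assert dt.background_rate(series, "det1", "OW") == pytest.approx(2.1)

    def test_background_rate_requires_background_frames(self):
        series = dt.MeasurementSeries([make_measurement(100)], [
            dt.RadioactiveSource("s1", 1e6, 0.0, 1e4)
        ])
        with pytest.raises(ValueError):
            dt.background_rate(series, "det1", "OW")


class TestDualSource:
    def test_combined_equal_to_sum_is_flagged_invalid(self):
        res = dt.dual_source_tau(100.0, 100.0, 200.0)
        assert res.tau == 0.0
        assert not res.valid

    def test_combined_above_sum_is_flagged_invalid(self):
        assert not dt.dual_source_tau(100.0, 100.0, 210.0).valid

    def test_exact_recovery_equal_sources(self):
        tau = 1.0e-6
        r1, r2, r12 = forward_triple(tau, 1e5, 1e5)
        assert r1 == pytest.approx(90483.7, abs=0.1)  # frozen forward values
        assert r12 == pytest.approx(163746.2, abs=0.1)
        res = dt.dual_source_tau(r1, r2, r12)
        assert res.valid
        assert res.tau == pytest.approx(tau, rel=1e-12)

    @pytest.mark.parametrize("product", [0.01, 0.1, 0.3, 0.6, 0.9])
    def test_equal_activity_estimate_is_exact_across_rates(self, product):
        tau = 1.3e-6
        rt = product / tau
        r1, r2, r12 = forward_triple(tau, rt / 2, rt / 2)
        assert dt.dual_source_tau(r1, r2, r12).tau == pytest.approx(tau, rel=1e-10)

    def test_unequal_sources_at_high_rate(self):
        # 44/56 activity split at total Rt*tau = 0.9 stays within 0.2%
        tau = 1.0e-6
        rt = 0.9 / tau
        r1, r2, r12 = forward_triple(tau, 0.44 * rt, 0.56 * rt)
        assert abs(dt.dual_source_tau(r1, r2, r12).tau - tau) / tau < 0.002

    def test_error_bound_values(self):
        assert dt.dual_source_error_bound(100.0, 100.0) == 0.0
        assert dt.dual_source_error_bound(44.0, 56.0) == pytest.approx(0.0036)
        assert dt.dual_source_error_bound(40.0, 60.0) == pytest.approx(0.01)

    def test_noiseless_error_within_low_rate_limit_plus_margin(self):
        """The estimator's relative error for unequal sources approaches
        (Rt1-Rt2)^2/(Rt1+Rt2)^2 as rates fall — four times the leading-order
        bound — and shrinks with rate; check err <= 4*bound + 0.5% over a
        wide grid of splits and rate levels."""
        tau = 1.0e-6
        for f in np.linspace(0.3, 0.7, 9):
            bound = dt.dual_source_error_bound(f, 1 - f)
            for level in np.linspace(0.35, 0.95, 7):
                r12 = level * dt.max_observed_rate(tau)
                rt12 = dt.correct_rate(r12, tau)
                r1, r2, _ = forward_triple(tau, f * rt12, (1 - f) * rt12)
                err = abs(dt.dual_source_tau(r1, r2, r12).tau - tau) / tau
                assert err <= 4 * bound + 0.005


class TestTripleSourceSchedule:
    def test_table1_pattern_yields_two_exact_estimates(self, table1_series):
        results = dt.triple_source_schedule(table1_series, "det1", "OW")
        assert len(results) == 2
        assert [round(r.total_activity / 1e6) for r in results] == [250, 500]
        for r in results:
            assert r.valid
            assert r.tau == pytest.approx(1.2e-6, rel=1e-6)

    def test_missing_three_source_frame_drops_one_result(self, table1_series):
        trimmed = dt.MeasurementSeries(
            [m for m in table1_series.measurements if m.source_ids != {"s1", "s2", "s3"}],
            table1_series.sources,
        )
        results = dt.triple_source_schedule(trimmed, "det1", "OW")
        assert len(results) == 1
        assert results[0].total_activity / 1e6 == pytest.approx(250.0)

    def test_intrinsic_preset_yields_one_estimate_per_combination(
        self, intrinsic_noiseless_series
    ):
        results = dt.triple_source_schedule(intrinsic_noiseless_series, "det1", "OW")
        # 9 full sessions x 2 combinations + 1 partial session x 1
        assert len(results) == 19
        in_range = [r for r in results if r.total_activity < 350e6]
        for r in in_range:
            assert abs(r.tau - 1.3e-6) / 1.3e-6 < 0.01  # decay alignment is first order


class TestGraphicalFit:
    def test_recovers_forward_model_exactly(self):
        c, tau = 7.8e-4, 1.3e-6
        a = np.linspace(10e6, 340e6, 25)
        pts = list(zip(a, a * c * np.exp(-a * c * tau)))
        fit = dt.graphical_fit(pts)
        assert fit.sensitivity == pytest.approx(c, rel=1e-9)
        assert fit.tau == pytest.approx(tau, rel=1e-9)
        assert fit.r_squared > 0.999999
        assert fit.n_used == 25 and fit.n_excluded == 0

    def test_no_dead_time_gives_zero_slope(self):
        a = np.linspace(10e6, 300e6, 10)
        fit = dt.graphical_fit(list(zip(a, 7.8e-4 * a)))
        assert fit.tau == pytest.approx(0.0, abs=1e-15)
        assert fit.sensitivity == pytest.approx(7.8e-4, rel=1e-12)

    def test_two_points_reproduce_closed_form_line(self):
        pts = [(100e6, 70e3), (200e6, 120e3)]
        y1, y2 = math.log(70e3 / 100e6), math.log(120e3 / 200e6)
        slope = (y2 - y1) / 100e6
        intercept = y1 - slope * 100e6
        fit = dt.graphical_fit(pts)
        assert fit.sensitivity == pytest.approx(math.exp(intercept), rel=1e-12)
        assert fit.tau == pytest.approx(-slope / math.exp(intercept), rel=1e-12)
        assert math.isnan(fit.se_tau)  # no residual dof with two points

    def test_nonpositive_points_are_excluded_and_counted(self):
        a = np.linspace(10e6, 300e6, 10)
        pts = list(zip(a, 7.8e-4 * a)) + [(50e6, 0.0), (0.0, 100.0)]
        fit = dt.graphical_fit(pts)
        assert fit.n_used == 10 and fit.n_excluded == 2

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(ValueError):
            dt.graphical_fit([(100e6, 70e3)])

    def test_poisson_tau_estimate_is_unbiased_within_one_se(self):
        """Across 200 seeded replicates of the intrinsic run, the mean tau
        estimate deviates from truth by less than one mean standard error."""
        taus, ses = [], []
        for seed in range(200):
            cfg = dt.make_intrinsic_preset(seed=seed, poisson_noise=True)
            series = dt.simulate_series(cfg)
            pts, _ = dt.pdm_validity_filter(
                dt.calibration_points(series, "det1", "OW"), activity_cutoff=350e6
            )
            fit = dt.graphical_fit(pts)
            taus.append(fit.tau)
            ses.append(fit.se_tau)
        bias = abs(np.mean(taus) - 1.3e-6)
        assert bias < np.mean(ses)

    def test_uncorrected_ambient_background_inflates_tau(self):
        """Skipping background subtraction biases the log-linear fit: the
        low-activity points sit too high, steepening the line and inflating
        both C and tau (the open-window 2.01 us vs 1.30 us effect)."""
        cfg = dt.make_intrinsic_preset(poisson_noise=False, background_ow=100.0)
        series = dt.simulate_series(cfg)
        bg = dt.background_rate(series, "det1", "OW")
        assert bg > 0
        raw_pts = [
            dt.CalibrationPoint(series.frame_activity(m), m.raw_rate, m.t_start)
            for m in series.frames("det1", "OW")
            if not m.is_background and series.frame_activity(m) < 350e6
        ]
        fit_raw = dt.graphical_fit(raw_pts)
        corrected, _ = dt.pdm_validity_filter(
            dt.calibration_points(series, "det1", "OW"), activity_cutoff=350e6
        )
        fit_net = dt.graphical_fit(corrected)
        assert fit_raw.tau > fit_net.tau
        assert fit_raw.sensitivity > fit_net.sensitivity


class TestMcr:
    def test_inverse_identity(self):
        assert dt.tau_from_mcr(dt.max_observed_rate(1.3e-6)) == pytest.approx(
            1.3e-6, rel=1e-12
        )

    def test_arithmetic_values(self):
        assert dt.tau_from_mcr(391.3e3) == pytest.approx(0.94e-6, rel=1e-3)
        assert dt.tau_from_mcr(282.9e3) == pytest.approx(1.30e-6, rel=1e-3)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            dt.tau_from_mcr(0.0)


class TestWindowFraction:
    def test_constant_fraction_has_zero_slope(self):
        pts = [(r, 0.6) for r in np.linspace(1e4, 2e5, 20)]
        fit = dt.window_fraction_fit(pts)
        assert fit.loss_pct_per_100kcps == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.6)

    def test_generator_slope_recovered_from_counts(self):
        cfg = dt.make_intrinsic_preset(poisson_noise=False, breakdown=None)
        res = dt.window_fraction_series(
            dt.simulate_series(cfg), "det1", "Tc", "OW"
        )
        # integer-count quantization limits agreement, not the estimator
        assert res.loss_pct_per_100kcps == pytest.approx(-9.5, abs=0.01)
        assert res.n_pairs == 49

    def test_unpaired_frames_are_skipped(self, table1_series):
        res_frames = table1_series.measurements + [
            dt.CountMeasurement("det1", "Tc", 1e6, 60.0, 1000, frozenset({"s1"}))
        ]
        series = dt.MeasurementSeries(res_frames, table1_series.sources)
        with pytest.raises(ValueError):
            # only one complete (OW, Tc) pair never exists here: all OW-only
            dt.window_fraction_series(series, "det1", "Tc", "OW")


class TestValidityFilter:
    def test_requires_a_cutoff(self, table1_series):
        pts = dt.calibration_points(table1_series, "det1", "OW")
        with pytest.raises(ValueError):
            dt.pdm_validity_filter(pts)

    def test_cutoff_above_all_points_excludes_nothing(self, table1_series):
        pts = dt.calibration_points(table1_series, "det1", "OW")
        inc, exc = dt.pdm_validity_filter(pts, activity_cutoff=1e12)
        assert len(inc) == len(pts) and not exc

    def test_breakdown_frames_are_exactly_the_excluded_ones(
        self, intrinsic_noiseless_series
    ):
        series = intrinsic_noiseless_series
        labelled = set(series.metadata["truth"]["breakdown_frames"])
        pts = dt.calibration_points(series, "det1", "OW")
        _, exc = dt.pdm_validity_filter(pts, activity_cutoff=350e6)
        assert {p.t_start for p in exc} == labelled

    def test_cutoff_below_all_points_breaks_downstream_fit(self, table1_series):
        pts = dt.calibration_points(table1_series, "det1", "OW")
        inc, _ = dt.pdm_validity_filter(pts, activity_cutoff=1.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            dt.graphical_fit(inc)

    def test_rate_cutoff_uses_open_window_rate(self, intrinsic_noiseless_series):
        pts = dt.calibration_points(intrinsic_noiseless_series, "det1", "Tc")
        inc, exc = dt.pdm_validity_filter(pts, ow_rate_cutoff=150e3)
        assert exc and all(p.ow_rate > 150e3 for p in exc)
        assert all(p.ow_rate <= 150e3 for p in inc)
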