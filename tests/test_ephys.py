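"""fEPSP metric suite: closed-form slope cases, generator parameter recovery,
scale invariance, I/O interpolation, stability screening, and time-course
normalization against a numerical-integration oracle."""

import numpy as np
import pytest
from scipy import integrate

from synaptect import ephys
from synaptect.ephys import (
    SweepSeries,
    baseline_stability,
    build_io_curve,
    fepsp_slope,
    fepsp_slope_trace,
    fiber_volley_amplitude,
    normalize_timecourse,
    percent_reduction,
    plasticity_magnitude,
    ppf_ratio,
    query_io,
)
from synaptect.synthetic import (
    TimeCourseSpec,
    TraceSpec,
    generate_io_series,
    generate_paired_pulse_trace,
    generate_plasticity_timecourse,
)


def single_sweep(v, khz=10.0, stims=(10.0,), protocol="IO", **kw):
    return SweepSeries(khz, np.asarray(v)[None, :], np.array([0.0]),
                       [list(stims)], protocol, **kw)


class TestSlopeAndVolley:
    def test_ideal_linear_ramp_slope_exact(self):
        # 1 mV fall over 1 ms starting 3 ms post-stimulus: slope exactly 1
        khz = 10.0
        t = np.arange(0, 400) / khz
        v = np.zeros_like(t)
        fall = (t >= 13.0) & (t < 14.0)
        v[fall] = -(t[fall] - 13.0)
        v[t >= 14.0] = -1.0
        assert fepsp_slope_trace(v, khz, 10.0) == pytest.approx(1.0, rel=1e-9)

    def test_flat_trace_is_unmeasurable_not_zero(self):
        assert np.isnan(fepsp_slope_trace(np.zeros(500), 10.0, 10.0))
        assert np.isnan(
            fiber_volley_amplitude(single_sweep(np.zeros(500)))
        )

    @pytest.mark.parametrize("slope", [0.34, 0.54, 1.0])
    def test_slope_parameter_recovered_noise_free(self, slope):
        series = generate_paired_pulse_trace(TraceSpec(fepsp_slope_mv_per_ms=slope))
        assert fepsp_slope(series) == pytest.approx(slope, rel=0.02)

    @pytest.mark.parametrize("volley", [0.15, 0.3])
    def test_volley_amplitude_recovered_and_linear(self, volley):
        series = generate_paired_pulse_trace(TraceSpec(volley_amp_mv=volley))
        assert fiber_volley_amplitude(series) == pytest.approx(volley, rel=0.02)

    def test_zero_volley_unmeasurable(self):
        series = generate_io_series(TraceSpec(volley_amp_mv=1e-9), [1.0])
        assert np.isnan(fiber_volley_amplitude(series))


class TestPPF:
    @pytest.mark.parametrize("factor", [1.0, 1.33, 1.42, 2.0])
    def test_ratio_recovers_facilitation_factor(self, factor):
        series = generate_paired_pulse_trace(TraceSpec(ppf_factor=factor))
        assert ppf_ratio(series) == pytest.approx(factor, rel=0.01)

    def test_ratio_invariant_to_amplitude_scaling(self):
        series = generate_paired_pulse_trace(TraceSpec(ppf_factor=1.4))
        scaled = SweepSeries(series.sampling_khz, series.sweeps * 3.7,
                             series.timestamps_s, series.stimulus_times_ms, "PPF")
        assert ppf_ratio(scaled) == pytest.approx(ppf_ratio(series), rel=1e-9)

    def test_unmeasurable_first_response_rejected(self):
        flat = single_sweep(np.zeros(1000), stims=(10.0, 50.0), protocol="PPF")
        with pytest.raises(ValueError, match="first response"):
            ppf_ratio(flat)

    def test_wrong_stimulus_count_rejected(self):
        series = generate_io_series(TraceSpec(), [1.0])
        with pytest.raises(ValueError, match="exactly 2"):
            ppf_ratio(series)


class TestIOCurve:
    def test_proportional_law_interpolates_exactly(self):
        spec = TraceSpec(volley_amp_mv=0.2, fepsp_slope_mv_per_ms=0.4)
        series = generate_io_series(spec, [0.5, 1.0, 1.5, 2.0])
        curve = build_io_curve(series)
        assert len(curve.points) == 4
        # proportional law: slope/volley constant => query is exact
        assert query_io(curve, 0.3) == pytest.approx(0.4 * 0.3 / 0.2, rel=0.02)

    def test_query_outside_range_rejected(self):
        curve = build_io_curve(generate_io_series(TraceSpec(), [1.0, 2.0]))
        with pytest.raises(ValueError, match="extrapolation"):
            query_io(curve, 10.0)

    def test_monotone_curve_gives_monotone_queries(self):
        curve = build_io_curve(generate_io_series(TraceSpec(), [0.5, 1.0, 2.0]))
        lo, hi = curve.points[0, 0], curve.points[-1, 0]
        qs = [query_io(curve, q) for q in np.linspace(lo, hi, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_reduced_gain_law_shows_expected_reduction_at_query(self):
        # a ~37% lower response gain at every volley reproduces a ~37%
        # reduction when both curves are queried at the same volley amplitude
        spec = TraceSpec(volley_amp_mv=0.2, fepsp_slope_mv_per_ms=0.54)
        wt = build_io_curve(generate_io_series(spec, [0.5, 1.0, 1.5, 2.0]))
        ko = build_io_curve(generate_io_series(spec, [0.5, 1.0, 1.5, 2.0],
                                               response_gain=0.63))
        red = percent_reduction(query_io(wt, 0.3), query_io(ko, 0.3))
        assert red == pytest.approx(37.0, abs=1.5)


class TestBaselineStability:
    def _series_with_factors(self, factors, interval_s=30.0):
        spec = TraceSpec()
        sweeps, stims = [], []
        khz = spec.sampling_khz
        n = int(round((spec.baseline_ms + spec.template_span_ms + 5.0) * khz))
        from synaptect.synthetic import _add_response

        for f in factors:
            v = np.zeros(n)
            _add_response(v, khz, spec.baseline_ms, spec, fepsp_gain=f)
            sweeps.append(v)
            stims.append([spec.baseline_ms])
        return SweepSeries(khz, np.vstack(sweeps),
                           np.arange(len(factors)) * interval_s, stims, "LTP")

    def test_flat_series_passes_with_zero_drift(self):
        res = baseline_stability(self._series_with_factors(np.ones(20)))
        assert res.passed and res.drift_pct == pytest.approx(0.0, abs=1e-6)

    def test_linear_rundown_fails_with_matching_drift(self):
        res = baseline_stability(self._series_with_factors(np.linspace(1.1, 0.9, 20)))
        assert not res.passed
        assert res.drift_pct == pytest.approx(-20.0, abs=1.0)

    def test_small_fluctuations_rarely_fail(self):
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            factors = 1.0 + rng.normal(0, 0.02, size=20)
            if baseline_stability(self._series_with_factors(factors)).passed:
                passes += 1
        assert passes >= 95


class TestTimecourse:
    def test_constant_series_is_flat_hundred(self):
        spec = TimeCourseSpec(plateau_pct=100.0, total_min=25.0)
        res = normalize_timecourse(generate_plasticity_timecourse(spec))
        np.testing.assert_allclose(res.normalized_pct, 100.0, atol=1e-6)

    def test_baseline_mean_exactly_hundred(self):
        spec = TimeCourseSpec(plateau_pct=150.0, transient_pct=40.0,
                              noise_sd_pct=5.0, total_min=30.0, seed=2)
        res = normalize_timecourse(generate_plasticity_timecourse(spec))
        assert res.normalized_pct[res.minutes < 0].mean() == pytest.approx(100.0, abs=1e-9)

    def test_scale_invariance(self):
        spec = TimeCourseSpec(plateau_pct=141.6, total_min=70.0)
        series = generate_plasticity_timecourse(spec)
        scaled = SweepSeries(series.sampling_khz, series.sweeps * 2.0,
                             series.timestamps_s, series.stimulus_times_ms,
                             "LTP", induction_time_s=series.induction_time_s)
        a = normalize_timecourse(series)
        b = normalize_timecourse(scaled)
        np.testing.assert_allclose(a.normalized_pct, b.normalized_pct, rtol=1e-7)

    @pytest.mark.parametrize("plateau,window", [(141.6, (50.0, 60.0)),
                                                (121.7, (50.0, 60.0)),
                                                (185.0, (0.0, 5.0))])
    def test_plateau_recovered_in_window(self, plateau, window):
        spec = TimeCourseSpec(plateau_pct=plateau, total_min=75.0)
        res = normalize_timecourse(generate_plasticity_timecourse(spec))
        assert plasticity_magnitude(res, window) == pytest.approx(plateau, rel=0.01)

    def test_exponential_window_mean_matches_integration_oracle(self):
        # transient 85% with tau = 2 min on a 100% plateau, averaged over the
        # first 5 min: compare against direct numerical integration
        # dense sweep sampling so that the discrete per-minute mean converges
        # to the continuous integral
        spec = TimeCourseSpec(protocol="PTP", plateau_pct=100.0, transient_pct=85.0,
                              transient_tau_min=2.0, total_min=20.0,
                              sweep_interval_s=2.0)
        res = normalize_timecourse(generate_plasticity_timecourse(spec))
        got = plasticity_magnitude(res, (0.0, 5.0))
        oracle, _ = integrate.quad(lambda t: 100.0 + 85.0 * np.exp(-t / 2.0), 0.0, 5.0)
        assert got == pytest.approx(oracle / 5.0, rel=0.005)

    def test_window_outside_recording_rejected(self):
        spec = TimeCourseSpec(plateau_pct=120.0, total_min=20.0)
        res = normalize_timecourse(generate_plasticity_timecourse(spec))
        with pytest.raises(ValueError, match="window"):
            plasticity_magnitude(res, (50.0, 60.0))

    def test_missing_induction_time_rejected(self):
        series = generate_io_series(TraceSpec(), [1.0, 1.0])
        with pytest.raises(ValueError, match="induction"):
            normalize_timecourse(series)


def test_percent_reduction_arithmetic():
    assert percent_reduction(0.54, 0.34) == pytest.approx(100 * (0.54 - 0.34) / 0.54)
    with pytest.raises(ValueError):
        percent_reduction(0.0, 1.0)
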