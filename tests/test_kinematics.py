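"""Curve smoothing, differentiation and stroke-timing feature extraction."""

import numpy as np
import pytest

from swimdyn import (
    CurveGeneratorConfig,
    FeatureNotFoundError,
    SampledCurve,
    differentiate,
    find_extrema,
    generate_cog_velocity_curve,
    generate_link_angular_velocity_curve,
    leg_retraction_lag,
    peak_to_valley_duration,
    smooth,
)


def sine_curve(freq=1.0, rate=50.0, duration=2.0, amp=1.0, noise=0.0, seed=0):
    t = np.arange(int(duration * rate) + 1) / rate
    y = amp * np.sin(2 * np.pi * freq * t)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, t.size)
    return SampledCurve(values=y, sampling_rate=rate)


class TestSmooth:
    def test_zero_parameter_is_identity(self):
        c = sine_curve()
        out = smooth(c, 0.0)
        assert np.allclose(out.values, c.values, atol=1e-8)

    def test_line_is_reproduced_for_any_parameter(self):
        t = np.arange(40) / 50.0
        c = SampledCurve(values=2.0 + 3.0 * t, sampling_rate=50.0)
        for s in (0.0, 0.5, 10.0):
            assert np.allclose(smooth(c, s).values, c.values, atol=1e-7)

    def test_reduces_noise_around_known_signal(self):
        rate, dur = 50.0, 2.0
        clean = sine_curve(rate=rate, duration=dur).values
        noisy = sine_curve(rate=rate, duration=dur, noise=0.05, seed=42)
        # residual budget ~ n * sigma^2 is the standard spline choice
        smoothed = smooth(noisy, noisy.values.size * 0.05**2)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(smoothed.values - clean) < rms(noisy.values - clean)

    def test_too_few_samples_rejected(self):
        c = SampledCurve(values=np.array([1.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            smooth(c, 0.0)


class TestDifferentiate:
    def test_constant_angle_gives_zero_velocity(self):
        c = SampledCurve(values=np.full(20, 35.0))
        assert np.allclose(differentiate(c).values, 0.0)

    def test_linear_ramp(self):
        # 90 degrees per second -> pi/2 rad/s everywhere
        t = np.arange(50) / 50.0
        c = SampledCurve(values=90.0 * t, sampling_rate=50.0)
        assert np.allclose(differentiate(c).values, np.pi / 2, rtol=1e-9)

    def test_sine_derivative_matches_cosine(self):
        rate = 200.0  # fine grid: O(dt^2) truncation
        t = np.arange(int(rate) + 1) / rate
        c = SampledCurve(values=np.degrees(np.sin(2 * np.pi * t)), sampling_rate=rate)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        got = differentiate(c).values
        assert np.allclose(got[1:-1], expected[1:-1], atol=2e-3)


class TestFindExtrema:
    def test_planted_single_peak(self):
        cfg = CurveGeneratorConfig(peak_time=0.30, peak_value=1.4)
        curve, truth = generate_cog_velocity_curve(cfg)
        feats = find_extrema(curve)
        assert feats.global_max_time == pytest.approx(0.30, abs=0.01)
        assert truth.peak_time == pytest.approx(0.30, abs=1e-12)

    def test_monotone_ramp_has_no_interior_peaks(self):
        c = SampledCurve(values=np.linspace(0, 1, 50))
        feats = find_extrema(c)
        assert feats.peak_times.size == 0
        assert feats.valley_times.size == 0

    def test_prominence_filters_smaller_peak(self):
        t = np.arange(101) / 50.0
        y = np.exp(-((t - 0.5) ** 2) / (2 * 0.05**2)) + 0.2 * np.exp(
            -((t - 1.5) ** 2) / (2 * 0.05**2)
        )
        c = SampledCurve(values=y, sampling_rate=50.0)
        feats = find_extrema(c, min_prominence=0.5)
        assert feats.peak_times.size == 1
        assert feats.peak_times[0] == pytest.approx(0.5, abs=0.01)

    def test_time_shift_equivariance(self):
        cfg = CurveGeneratorConfig(peak_time=0.30, peak_value=1.4)
        curve, _ = generate_cog_velocity_curve(cfg)
        shifted = SampledCurve(
            values=curve.values, sampling_rate=curve.sampling_rate, start_time=10.0
        )
        a, b = find_extrema(curve), find_extrema(shifted)
        assert b.global_max_time == pytest.approx(a.global_max_time + 10.0)
        assert np.allclose(b.peak_times, a.peak_times + 10.0)
        assert np.allclose(b.peak_values, a.peak_values)

    def test_amplitude_scale_leaves_times_unchanged(self):
        cfg = CurveGeneratorConfig(peak_time=0.30, peak_value=1.4)
        curve, _ = generate_cog_velocity_curve(cfg)
        scaled = SampledCurve(values=3.0 * curve.values, sampling_rate=50.0)
        a, b = find_extrema(curve), find_extrema(scaled)
        assert np.allclose(a.peak_times, b.peak_times)
        assert a.global_max_time == b.global_max_time


class TestTimingMetrics:
    @pytest.mark.parametrize(
        "event, expected_lag", [(0.48, -0.02), (0.50, 0.0), (0.44, -0.06)]
    )
    def test_leg_retraction_lag_fixtures(self, event, expected_lag):
        """Constructed cycles mirroring the measured early-retraction lags."""
        cfg = CurveGeneratorConfig(peak_time=0.50, peak_value=1.45)
        curve, _ = generate_cog_velocity_curve(cfg)
        assert leg_retraction_lag(curve, event) == pytest.approx(
            expected_lag, abs=1e-9
        )

    def test_event_outside_span_rejected(self):
        curve, _ = generate_cog_velocity_curve(CurveGeneratorConfig())
        with pytest.raises(ValueError):
            leg_retraction_lag(curve, 5.0)

    def test_peak_to_valley_fixture(self):
        """Peak at 0.20 s, deepest valley at 0.66 s -> 0.46 s exactly."""
        cfg = CurveGeneratorConfig(peak_time=0.20, peak_value=6.0)
        curve, truth = generate_link_angular_velocity_curve(cfg, 0.66)
        assert peak_to_valley_duration(curve) == pytest.approx(0.46, abs=1e-9)
        assert truth.valley_time == pytest.approx(0.66)

    def test_symmetric_tent(self):
        t = np.arange(101) / 50.0
        y = 1.0 - np.abs(t - 1.0)  # peak at centre, minima at the ends
        # pad with end dips so the ends register as valleys
        c = SampledCurve(values=np.concatenate([[0.1], y, [0.1]]),
                         sampling_rate=50.0)
        d = peak_to_valley_duration(c)
        assert d == pytest.approx(1.0, abs=1e-9)  # half-span of the tent

    def test_valley_only_before_peak_is_not_found(self):
        t = np.arange(101) / 50.0
        y = np.where(t < 1.0, -np.exp(-((t - 0.5) ** 2) / 0.005),
                     np.exp(-((t - 1.5) ** 2) / 0.005))
        c = SampledCurve(values=y, sampling_rate=50.0)
        with pytest.raises(FeatureNotFoundError):
            peak_to_valley_duration(c)


class TestRecovery:
    def test_noise_free_recovery_within_half_sample(self):
        for pt in (0.14, 0.30, 0.62):
            curve, truth = generate_cog_velocity_curve(
                CurveGeneratorConfig(peak_time=pt, peak_value=1.4)
            )
            feats = find_extrema(curve)
            assert abs(feats.global_max_time - truth.peak_time) <= 0.5 / 50.0

    def test_noisy_recovery_within_two_samples(self):
        cfg = CurveGeneratorConfig(
            peak_time=0.50, peak_value=1.45, noise_sd=0.05 * 1.45, seed=7
        )
        curve, truth = generate_cog_velocity_curve(cfg)
        sm = smooth(curve, curve.values.size * (0.05 * 1.45) ** 2)
        feats = find_extrema(sm)
        assert abs(feats.global_max_time - truth.peak_time) <= 2.0 / 50.0
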