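"""Rates, bump fitting and drift metrics against hand-computed oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebpb import analysis
from ebpb.analysis import (BumpTrajectory, bump_deviation, bump_speed,
                           exponential_rate, fit_bump, fit_sqrt_drift,
                           track_loss, unwrap_centers, wrap_deg)
from ebpb.config import default_config
from ebpb.protocols import OrientationTrace, position_to_azimuth

CFG = default_config()


class TestExponentialRate:
    def test_no_spikes(self):
        r = exponential_rate(np.array([]), np.arange(0, 1000.0, 10.0), 10, 721.5)
        assert np.all(r == 0)

    def test_single_spike_amplitude_and_decay(self):
        grid = np.array([100.0, 100.0 + 721.5])
        r = exponential_rate(np.array([100.0]), grid, 10, 721.5)
        assert r[0] == pytest.approx(0.1)
        assert r[1] == pytest.approx(0.1 / math.e, rel=1e-9)

    def test_half_life_500ms(self):
        grid = np.array([0.0, 500.0])
        r = exponential_rate(np.array([0.0]), grid, 1, 721.5)
        assert r[1] / r[0] == pytest.approx(0.5, abs=1e-4)

    def test_causality(self):
        grid = np.array([0.0, 99.0, 101.0])
        r = exponential_rate(np.array([100.0]), grid, 1, 721.5)
        assert r[0] == 0 and r[1] == 0 and r[2] > 0

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0, 900), min_size=0, max_size=30))
    def test_linearity_over_spike_sets(self, times):
        """The kernel rate of a merged spike set is the sum of the parts."""
        times = np.asarray(times)
        grid = np.arange(0.0, 1000.0, 50.0)
        a, b = times[::2], times[1::2]
        r_all = exponential_rate(times, grid, 1, 721.5)
        r_sum = exponential_rate(a, grid, 1, 721.5) + \
            exponential_rate(b, grid, 1, 721.5)
        assert np.allclose(r_all, r_sum, atol=1e-9)


def wrapped_gaussian_profile(center_pos, sigma_wedges, height=30.0, base=0.0):
    x = np.arange(16.0)
    dx = (x - center_pos + 8) % 16 - 8
    return base + height * np.exp(-0.5 * (dx / sigma_wedges) ** 2)


class TestFitBump:
    def test_recovers_noise_free_gaussian(self):
        sigma = 24.8 / 22.5  # FWHM 58.4 deg
        y = wrapped_gaussian_profile(5.0, sigma)
        c, fwhm, h, ok = fit_bump(y, CFG)
        assert ok
        assert fwhm == pytest.approx(58.4, rel=0.01)
        assert h == pytest.approx(30.0, rel=0.02)
        assert wrap_deg(c - position_to_azimuth(5.0)) == pytest.approx(0.0, abs=0.5)

    def test_uniform_profile_not_ok(self):
        assert fit_bump(np.full(16, 7.0), CFG)[3] is False

    def test_subthreshold_bump_not_ok(self):
        y = wrapped_gaussian_profile(3.0, 1.0, height=0.5)
        assert not fit_bump(y, CFG)[3]

    def test_low_contrast_rejected(self):
        y = wrapped_gaussian_profile(3.0, 1.0, height=5.0, base=100.0)
        assert not fit_bump(y, CFG)[3]

    def test_rotation_equivariance_exact(self):
        """Rotating the rate map by k wedges shifts the fitted center by
        exactly k * 22.5 deg (in the wedge-position sense)."""
        y = wrapped_gaussian_profile(4.0, 1.2)
        c0 = fit_bump(y, CFG)[0]
        for k in (1, 3, 7, 11):
            ck = fit_bump(np.roll(y, k), CFG)[0]
            # rolling forward moves the peak to a higher position, i.e.
            # azimuth decreases by k * 22.5
            assert wrap_deg(ck - (c0 - 22.5 * k)) == pytest.approx(0.0, abs=1e-6)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            fit_bump(np.zeros(8), CFG)


def make_traj(t_ms, centers, ok=None):
    n = len(t_ms)
    return BumpTrajectory(np.asarray(t_ms, float), np.asarray(centers, float),
                          np.full(n, 50.0), np.full(n, 30.0),
                          np.ones(n, bool) if ok is None else np.asarray(ok))


class TestDeviation:
    def test_perfect_tracking_is_zero(self):
        t = np.arange(0, 5000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 123.0))
        dev, sd = bump_deviation(make_traj(t, np.full_like(t, 123.0)), truth)
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        t = np.arange(0, 2000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        dev, _ = bump_deviation(make_traj(t, np.full_like(t, 90.0)), truth)
        assert dev == pytest.approx(math.pi / 2)

    def test_bounded_by_pi(self):
        t = np.arange(0, 2000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        dev, _ = bump_deviation(make_traj(t, np.full_like(t, 180.0)), truth)
        assert dev <= math.pi + 1e-12

    def test_failed_fits_excluded_and_empty_window_raises(self):
        t = np.arange(0, 1000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        traj = make_traj(t, np.full_like(t, 90.0), ok=np.zeros(len(t), bool))
        with pytest.raises(ValueError):
            bump_deviation(traj, truth)


class TestSpeed:
    def test_stationary(self):
        t = np.arange(0, 3000.0, 100.0)
        assert bump_speed(make_traj(t, np.full_like(t, 50.0)), (0, 3000)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_known_slope_through_wrap(self):
        t = np.arange(0, 4000.0, 100.0)
        c = (10.0 - 58.5 * t / 1000.0) % 360.0  # clockwise at 58.5 deg/s
        sp = bump_speed(make_traj(t, c), (0, 4000))
        assert sp == pytest.approx(-58.5, rel=1e-6)

    def test_jump_samples_dropped(self):
        t = np.arange(0, 1000.0, 100.0)
        c = np.full_like(t, 10.0)
        c[5] = 170.0  # a 160 deg glitch
        ts, cs = unwrap_centers(t, c, np.ones(len(t), bool))
        assert len(ts) == len(t) - 1

    def test_insufficient_fits_raise(self):
        t = np.arange(0, 1000.0, 100.0)
        traj = make_traj(t, np.full_like(t, 0.0), ok=np.zeros(len(t), bool))
        with pytest.raises(ValueError):
            bump_speed(traj, (0, 1000))


class TestTrackLoss:
    def test_tight_tracking_no_loss(self):
        t = np.arange(0, 5000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        assert not track_loss(make_traj(t, np.full_like(t, 10.0)), truth, CFG)

    def test_sustained_large_error_is_loss(self):
        t = np.arange(0, 5000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        c = np.full_like(t, 10.0)
        c[20:] = 100.0  # > 45 deg away for > 1 s
        assert track_loss(make_traj(t, c), truth, CFG)

    def test_brief_excursion_is_not_loss(self):
        t = np.arange(0, 5000.0, 100.0)
        truth = OrientationTrace(t, np.full_like(t, 0.0))
        c = np.full_like(t, 0.0)
        c[20:25] = 100.0  # only 0.5 s
        assert not track_loss(make_traj(t, c), truth, CFG)


class TestSqrtDrift:
    def test_exact_recovery(self):
        t = np.linspace(0.5, 100.0, 200)
        fit = fit_sqrt_drift(t, np.sqrt(0.05 * t))
        assert fit.a == pytest.approx(0.05, rel=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)

    def test_zero_deviation(self):
        t = np.linspace(0.5, 100.0, 50)
        assert fit_sqrt_drift(t, np.zeros_like(t)).a == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_sqrt_drift(np.array([1.0]), np.array([-0.1]))

    @settings(derandomize=True, max_examples=20)
    @given(a=st.floats(1e-4, 1.0))
    def test_recovery_across_scales(self, a):
        t = np.linspace(0.1, 60.0, 100)
        assert fit_sqrt_drift(t, np.sqrt(a * t)).a == pytest.approx(a, rel=1e-6)


class TestWrap:
    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(-1000, 1000))
    def test_wrap_range_and_consistency(self, x):
        w = float(wrap_deg(x))
        assert -180.0 < w <= 180.0
        assert (x - w) % 360.0 == pytest.approx(0.0, abs=1e-6) or \
               (x - w) % 360.0 == pytest.approx(360.0, abs=1e-6)
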