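"""Peak detection, integration and model-fit contracts."""

import numpy as np
import pytest

import projprof as pp
from projprof.shapes import egh, gaussian, gaussian_area, egh_area


def two_gaussian_profile(noise_sd=0.0, seed=0, shift=0.0):
    t = np.linspace(0, 10, 1500) + shift
    y = gaussian(t, 100.0, 3.0 + shift, 0.1) + gaussian(t, 50.0, 7.0 + shift, 0.12)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return pp.Profile(t, y)


class TestSmoothing:
    def test_constant_unchanged(self):
        y = np.full(100, 4.0)
        np.testing.assert_allclose(pp.smooth_pseudo_gaussian(y, 5), y)

    def test_impulse_mass_conserved(self):
        y = np.zeros(101)
        y[50] = 1.0
        out = pp.smooth_pseudo_gaussian(y, 3)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[50] == out.max()

    def test_noise_variance_reduced(self, rng):
        y = rng.normal(size=2000)
        out = pp.smooth_pseudo_gaussian(y, 5)
        assert out.var() < 0.5 * y.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pp.smooth_pseudo_gaussian(np.zeros(50), 4)


class TestDetection:
    def test_two_separated_peaks_found(self):
        prof = two_gaussian_profile(noise_sd=0.5)  # SNR 200 and 100
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        assert len(peaks) == 2
        step = prof.time[1] - prof.time[0]
        assert abs(peaks[0].apex_time - 3.0) <= step
        assert abs(peaks[1].apex_time - 7.0) <= step

    def test_flat_profile_yields_nothing(self):
        prof = pp.Profile(np.linspace(0, 10, 500), np.zeros(500))
        assert pp.detect_peaks(prof, pp.DetectionParams()) == []

    def test_min_height_threshold_filters(self):
        prof = two_gaussian_profile()
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=60.0))
        assert len(peaks) == 1 and abs(peaks[0].apex_time - 3.0) < 0.1

    def test_translation_equivariance(self):
        det = pp.DetectionParams(min_height=5.0)
        base = pp.detect_peaks(two_gaussian_profile(), det)
        moved = pp.detect_peaks(two_gaussian_profile(shift=2.5), det)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            assert b.apex_time - a.apex_time == pytest.approx(2.5, abs=1e-9)


class TestIntegration:
    def test_pd_isolated_gaussian_matches_closed_form(self):
        prof = two_gaussian_profile()
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.integrate_pd(prof, peaks)
        assert peaks[0].area_pd == pytest.approx(gaussian_area(100.0, 0.1),
                                                 rel=5e-3)

    def test_pd_cluster_conservation(self):
        """Two fused peaks: the PD areas sum to the total cluster area."""
        t = np.linspace(0, 6, 1200)
        y = gaussian(t, 80.0, 2.8, 0.15) + gaussian(t, 60.0, 3.3, 0.15)
        prof = pp.Profile(t, y)
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        assert len(peaks) == 2
        pp.integrate_pd(prof, peaks)
        lo, hi = peaks[0].left_idx, peaks[1].right_idx
        total = np.trapezoid(np.clip(y[lo:hi + 1], 0, None), t[lo:hi + 1])
        assert peaks[0].area_pd + peaks[1].area_pd == pytest.approx(total,
                                                                    abs=1e-9)

    def test_ts_close_to_pd_on_zero_baseline(self):
        prof = two_gaussian_profile()
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.integrate_pd(prof, peaks)
        pp.integrate_ts(prof, peaks)
        for p in peaks:
            assert p.area_ts == pytest.approx(p.area_pd, rel=0.01)
            assert p.area_ts <= p.area_pd + 1e-12

    def test_ts_independent_of_linear_ramp(self):
        t = np.linspace(0, 6, 1200)
        det = pp.DetectionParams(min_height=5.0)
        areas = []
        for slope in (0.0, 2.0):
            prof = pp.Profile(t, gaussian(t, 100.0, 3.0, 0.1) + slope * t)
            peaks = pp.detect_peaks(prof, det)
            pp.integrate_ts(prof, peaks)
            areas.append(peaks[0].area_ts)
        assert areas[1] == pytest.approx(areas[0], rel=0.01)

    def test_flat_top_between_equal_valleys_has_zero_ts_area(self):
        t = np.linspace(0, 1, 101)
        prof = pp.Profile(t, np.full(101, 3.0))
        peak = pp.Peak(apex_time=0.5, apex_height=3.0, h_prime=0.0,
                       left_border=0.0, right_border=1.0,
                       left_idx=0, apex_idx=50, right_idx=100)
        pp.integrate_ts(prof, [peak])
        assert peak.area_ts == 0.0


class TestModelFits:
    def test_gaussian_fit_recovers_parameters(self):
        t = np.linspace(8, 12, 600)
        prof = pp.Profile(t, gaussian(t, 50.0, 10.0, 0.1))
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.fit_gaussian_peak(prof, peaks[0])
        h, t_r, sigma = peaks[0].fit_gaussian
        assert h == pytest.approx(50.0, rel=1e-3)
        assert t_r == pytest.approx(10.0, abs=1e-3)
        assert sigma == pytest.approx(0.1, rel=1e-3)
        assert peaks[0].area_gauss == pytest.approx(gaussian_area(50.0, 0.1),
                                                    rel=1e-3)

    def test_gaussian_fit_biased_on_tailed_peak(self):
        """Strong tailing (tau = 3 sigma_g): the symmetric model misses the
        true area by more than 2% — the documented Gaussian-fit bias."""
        t = np.linspace(0, 8, 1200)
        y = egh(t, 100.0, 3.0, 0.1, 0.3)
        prof = pp.Profile(t, y)
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.fit_gaussian_peak(prof, peaks[0])
        true_area = np.trapezoid(y, t)
        assert abs(peaks[0].area_gauss - true_area) / true_area > 0.02

    def test_too_few_points_leaves_fit_absent(self):
        t = np.linspace(0, 1, 3)
        prof = pp.Profile(t, np.array([0.0, 1.0, 0.0]))
        peak = pp.Peak(apex_time=0.5, apex_height=1.0, h_prime=1.0,
                       left_border=0.0, right_border=1.0,
                       left_idx=0, apex_idx=1, right_idx=2)
        pp.fit_gaussian_peak(prof, peak)
        assert peak.fit_gaussian is None and peak.area_gauss is None

    def test_egh_reduces_to_gaussian_at_zero_tau(self):
        t = np.linspace(8, 12, 600)
        prof = pp.Profile(t, gaussian(t, 50.0, 10.0, 0.1))
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.fit_gaussian_peak(prof, peaks[0])
        pp.fit_egh_peak(prof, peaks[0])
        assert peaks[0].area_egh == pytest.approx(peaks[0].area_gauss,
                                                  rel=1e-3)

    def test_egh_fit_recovers_parameters(self):
        t = np.linspace(0, 6, 900)
        prof = pp.Profile(t, egh(t, 100.0, 3.0, 0.08, 0.05))
        peaks = pp.detect_peaks(prof, pp.DetectionParams(min_height=5.0))
        pp.fit_egh_peak(prof, peaks[0])
        h, t_r, sigma_g, tau = peaks[0].fit_egh
        assert h == pytest.approx(100.0, rel=0.01)
        assert t_r == pytest.approx(3.0, abs=0.01)
        assert sigma_g == pytest.approx(0.08, rel=0.01)
        assert tau == pytest.approx(0.05, rel=0.01)

    def test_egh_support_rule_is_exactly_zero(self):
        # pick t where the denominator 2 sigma_g^2 + tau (t - t_R) = -0.01
        sigma_g, tau, t_r = 0.08, 0.05, 3.0
        t_zero = t_r + (-0.01 - 2 * sigma_g**2) / tau
        assert egh(np.array([t_zero]), 100.0, t_r, sigma_g, tau)[0] == 0.0

    def test_egh_area_matches_quadrature_of_dense_samples(self):
        t = np.linspace(0, 10, 20000)
        y = egh(t, 100.0, 4.0, 0.1, 0.08)
        assert egh_area(100.0, 4.0, 0.1, 0.08) == pytest.approx(
            np.trapezoid(y, t), rel=1e-4)
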