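"""Baseline-correction contracts: Whittaker oracle equivalence, conservation,
per-method behavior on signals with known backgrounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import projprof as pp
from projprof.baselines import (METHODS, backcor_baseline, correct_profile,
                                default_params, lmv_rsa_baseline,
                                morphological_opening, swima_baseline)
from projprof.shapes import gaussian


def dense_whittaker(y, w, lam, order):
    """Brute-force dense normal-equation solve (the oracle)."""
    n = y.size
    d = np.eye(n)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return np.linalg.solve(np.diag(w) + lam * d.T @ d, w * y)


class TestWhittaker:
    def test_tiny_lambda_returns_signal(self, rng):
        y = rng.normal(size=80)
        z = pp.whittaker_solve(y, np.ones(80), 1e-12, 2)
        np.testing.assert_allclose(z, y, atol=1e-9)

    def test_straight_line_in_null_space(self):
        t = np.linspace(0, 1, 200)
        y = 3 * t + 2
        z = pp.whittaker_solve(y, np.ones(200), 1e12, 2)
        np.testing.assert_allclose(z, y, atol=1e-6)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_dense_solve(self, order, rng):
        y = rng.normal(size=50)
        w = rng.uniform(0.1, 1.0, size=50)
        lam = 10.0
        z = pp.whittaker_solve(y, w, lam, order)
        np.testing.assert_allclose(z, dense_whittaker(y, w, lam, order),
                                   atol=1e-8)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            pp.whittaker_solve(np.ones(10), np.zeros(10), 1.0, 2)


def _noisy_sloped_profile(rng, noise_sd=0.05):
    t = np.linspace(0, 10, 1200)
    base = 4.0 + 0.6 * t
    return t, base, base + rng.normal(0, noise_sd, t.size)


@pytest.mark.parametrize("method", METHODS)
class TestEveryMethod:
    def test_zero_input_gives_zero_baseline(self, method):
        res = correct_profile(np.zeros(300), default_params(method))
        np.testing.assert_allclose(res.baseline, 0.0, atol=1e-9)

    def test_conservation(self, method, rng):
        _, _, y = _noisy_sloped_profile(rng)
        y = y + gaussian(np.linspace(0, 10, 1200), 80.0, 5.0, 0.12)
        res = correct_profile(y, default_params(method))
        np.testing.assert_allclose(res.corrected + res.baseline, y, atol=1e-9)
        assert res.weights.min() >= 0.0 and res.weights.max() <= 1.0


@pytest.mark.parametrize("method", ["ALS", "arPLS"])
def test_pls_recovers_linear_baseline_within_noise(method, rng):
    """Peak-free sloped signal: the estimated baseline tracks the true line
    to within 3 noise SDs everywhere (ALS sits near the lower noise
    envelope by construction; arPLS near the noise mean)."""
    _, base, y = _noisy_sloped_profile(rng, noise_sd=0.05)
    res = correct_profile(y, default_params(method))
    assert np.abs(res.baseline - base).max() < 3 * 0.05


def test_roughness_non_increasing_in_lambda(rng):
    """PLS-family smoothness: baseline roughness falls as lam grows."""
    _, _, y = _noisy_sloped_profile(rng)
    y = y + gaussian(np.linspace(0, 10, 1200), 50.0, 5.0, 0.1)
    rough = []
    for lam in [1e2, 1e4, 1e6, 1e8]:
        params = pp.BaselineParams(method="ALS", lam=lam, p=5e-6)
        z = correct_profile(y, params).baseline
        rough.append(np.sum(np.diff(z, 2) ** 2))
    assert all(a >= b - 1e-12 for a, b in zip(rough, rough[1:]))


class TestBackcor:
    def test_exact_polynomial_is_reproduced(self):
        t = np.linspace(-1, 1, 400)
        y = 2 + 0.5 * t - 1.5 * t**2 + 0.3 * t**3 + 0.8 * t**4
        res = backcor_baseline(y, pp.BaselineParams(method="backcor", order=4))
        assert np.abs(res.baseline - y).max() < 1e-6

    def test_unknown_cost_function_rejected(self):
        with pytest.raises(ValueError, match="cost_fct"):
            backcor_baseline(np.ones(50),
                             pp.BaselineParams(method="backcor", order=4,
                                               cost_fct="nope"))

    def test_peak_on_polynomial_background(self, rng):
        t = np.linspace(0, 10, 800)
        base = 5 + 0.4 * t - 0.03 * t**2
        y = base + gaussian(t, 60.0, 5.0, 0.15) + rng.normal(0, 0.05, 800)
        res = backcor_baseline(y, default_params("backcor"))
        off = np.abs(t - 5) > 1.5
        assert np.abs(res.baseline - base)[off].max() < 0.3


class TestMorphology:
    def test_opening_preserves_constant(self):
        y = np.full(200, 7.0)
        np.testing.assert_array_equal(morphological_opening(y, 10), y)

    def test_opening_removes_narrow_triangle(self):
        y = np.zeros(200)
        y[95:106] = np.concatenate([np.arange(1, 7), np.arange(5, 0, -1)])
        assert np.abs(morphological_opening(y, 20)).max() == 0.0

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            morphological_opening(np.zeros(10), 10)


class TestLmvRsa:
    def test_monotone_ramp_is_its_own_baseline(self):
        t = np.linspace(0, 10, 600)
        y = 1.0 + 0.5 * t
        res = lmv_rsa_baseline(y, default_params("LMV_RSA"))
        assert np.abs(res.baseline - y).max() < 1e-6

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lmv_rsa_baseline(np.zeros(50), pp.BaselineParams(
                method="LMV_RSA", window=100))


class TestSwima:
    def test_constant_is_fixed_point(self):
        res = swima_baseline(np.full(60, 3.0))
        np.testing.assert_allclose(res.baseline, 3.0, atol=1e-12)

    def test_concave_peak_stripped_to_chord(self):
        """A 21-point triangle is stripped to the line joining its endpoints
        (the chord) to within 5% of the area above the chord."""
        x = np.arange(21.0)
        tri = 10.0 - np.abs(x - 10.0)
        res = swima_baseline(tri)
        chord = np.zeros(21)
        stripped = np.sum(tri - res.baseline)
        assert stripped == pytest.approx(np.sum(tri - chord), rel=0.05)

    def test_linear_drift_untouched(self):
        t = np.linspace(0, 10, 500)
        y = 2 + 0.8 * t
        res = swima_baseline(y)
        assert np.abs(res.corrected).max() < 1e-8


class TestCorrectCube:
    def test_zero_cube_gives_zero_baselines(self):
        cube = pp.DADCube(np.arange(50) * 0.4, np.arange(200.0, 210.0),
                          np.zeros((50, 10)))
        corrected, baseline = pp.correct_cube(cube, default_params("ALS"))
        np.testing.assert_allclose(baseline.absorbance, 0.0, atol=1e-9)

    def test_additivity_on_random_cube(self, rng):
        cube = pp.DADCube(np.arange(120) * 0.4, np.arange(200.0, 212.0),
                          rng.normal(10, 2, size=(120, 12)))
        corrected, baseline = pp.correct_cube(cube, default_params("arPLS"))
        np.testing.assert_allclose(
            corrected.absorbance + baseline.absorbance, cube.absorbance,
            atol=1e-9)

    def test_channel_error_names_wavelength(self):
        cube = pp.DADCube(np.arange(20) * 0.4, np.arange(200.0, 203.0),
                          np.zeros((20, 3)))
        bad = pp.BaselineParams(method="LMV_RSA", window=100)  # window > n
        with pytest.raises(RuntimeError, match="200"):
            pp.correct_cube(cube, bad)

    def test_corrected_matches_pure_signal(self, small_spec, small_cube,
                                           corrected_small_cube):
        """At each compound's lambda_max the corrected channel reproduces the
        noise-free pure signal (all compounds' spectral contributions at that
        wavelength) within a few noise SDs (RMS).

        The bound is 4 sigma: the retained noise contributes 1 sigma, and
        asymmetric ALS deliberately rests the baseline on the lower noise
        envelope, adding a systematic offset of about 2 sigma.  The first
        half minute is excluded — the solvent front is steepest there and
        every baseline estimator shows an edge transient.
        """
        from projprof.shapes import egh
        from projprof.synthetic import spectrum_value
        cube, truth = small_cube
        corrected, _ = corrected_small_cube
        sel = cube.time >= 0.5
        for comp in small_spec.compounds:
            j = int(np.argmin(np.abs(cube.wavelength - comp.lambda_max)))
            lam = cube.wavelength[j]
            pure = np.zeros_like(cube.time)
            for other in small_spec.compounds:
                trace = egh(cube.time, other.height, other.retention_time,
                            other.sigma_g, other.tau)
                pure += trace * float(spectrum_value(other.spectrum_bands, lam))
            diff = (corrected.absorbance[:, j] - pure)[sel]
            rms = np.sqrt(np.mean(diff ** 2))
            assert rms < 4 * small_spec.noise_sd


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_whittaker_oracle_property(seed):
    """Banded and dense solves agree on random small instances."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 100))
    y = rng.normal(size=n)
    w = rng.uniform(0.05, 1.0, size=n)
    lam = 10 ** rng.uniform(-2, 6)
    order = int(rng.integers(1, 4))
    z = pp.whittaker_solve(y, w, lam, order)
    np.testing.assert_allclose(z, dense_whittaker(y, w, lam, order), atol=1e-6)
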