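"""Peak detection, Lorentzian fitting and noise-based error estimation."""

import itertools

import numpy as np
import pytest

import specquant as sq
from specquant.peakfit import estimate_noise, integral_error_15n, lorentzian

from conftest import GREY_WINDOW


def flat_spectrum(intensity=None, n=4096, sigma=0.0, seed=0, rescaled=True):
    """Spectrum on a 16 ppm axis with supplied or Gaussian intensities."""
    params = sq.AcquisitionParams(n_points=n)
    ppm = np.linspace(12.7, 12.7 - 16.0 * (n - 1) / n, n)
    if intensity is None:
        rng = np.random.default_rng(seed)
        intensity = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    return sq.Spectrum1D(params=params, ppm=ppm, intensity=intensity, rescaled=rescaled)


def lorentzian_spectrum(lines, sigma=0.0, seed=0, n=4096):
    """Spectrum holding analytic Lorentzians given as (center, fwhm_ppm, height)."""
    spec = flat_spectrum(n=n, sigma=sigma, seed=seed)
    for c, w, h in lines:
        spec.intensity = spec.intensity + lorentzian(spec.ppm, c, w, h)
    return spec


class TestDetectPeaks:
    def test_all_zero_spectrum_returns_empty_with_warning(self):
        spec = flat_spectrum()
        with pytest.warns(UserWarning, match="no peaks"):
            assert sq.detect_peaks(spec, threshold=1.0) == []

    def test_noiseless_triplet_found_at_generator_positions(self):
        sample = sq.AmmoniumSample(conc_14n_mM=30.0)
        spec = sq.rescale(sq.simulate_1h_spectrum(sample))
        centers = sq.detect_peaks(spec, window_ppm=GREY_WINDOW)
        assert len(centers) == 3
        spacing = sample.j_nh_hz / spec.params.sfo_mhz
        expected = [sample.shift_ppm + spacing, sample.shift_ppm,
                    sample.shift_ppm - spacing]
        np.testing.assert_allclose(centers, expected, atol=spec.dppm)

    def test_threshold_above_maximum_returns_empty(self):
        spec = lorentzian_spectrum([(7.1, 0.01, 5.0)])
        with pytest.warns(UserWarning):
            assert sq.detect_peaks(spec, threshold=10.0) == []

    def test_manual_positions_merged_and_deduplicated(self):
        spec = lorentzian_spectrum([(7.1, 0.01, 5.0)])
        centers = sq.detect_peaks(spec, threshold=1.0,
                                  manual_ppm=[7.1, 3.0])  # 7.1 duplicates the maximum
        assert len(centers) == 2
        assert any(abs(c - 3.0) < 1e-9 for c in centers)

    def test_unrescaled_spectrum_rejected(self):
        spec = flat_spectrum(rescaled=False)
        with pytest.raises(ValueError, match="rescaled"):
            sq.detect_peaks(spec, threshold=1.0)


class TestFitLorentzians:
    def test_single_noiseless_line_recovered_to_machine_precision(self):
        w = 3.0 / 600.13  # 3 Hz in ppm
        spec = lorentzian_spectrum([(7.1, w, 1.0)])
        res = sq.fit_lorentzians(spec, [7.105], GREY_WINDOW)
        (peak,) = res.peaks
        assert peak.amplitude == pytest.approx(1.0, rel=1e-6)
        assert peak.fwhm_ppm == pytest.approx(w, rel=1e-6)
        assert peak.integral == pytest.approx(np.pi * 1.0 * w / 2.0, rel=1e-6)

    def test_two_overlapping_lines_match_grid_search_oracle(self):
        # truth: two lines separated by 1.5 x FWHM, heights 1.0 and 0.6
        w = 6.0 / 600.13
        c1, c2 = 7.05, 7.05 + 1.5 * w
        spec = lorentzian_spectrum([(c1, w, 1.0), (c2, w, 0.6)])
        mask = spec.window(*GREY_WINDOW)
        x, y = spec.ppm[mask], spec.intensity[mask]

        # coarse brute-force oracle over (c1, c2, w, a1, a2), then local
        # Nelder-Mead refinement -- an optimizer path independent of lmfit
        from scipy.optimize import minimize

        def sse(p):
            model = lorentzian(x, p[0], p[2], p[3]) + lorentzian(x, p[1], p[2], p[4])
            return np.sum((model - y) ** 2)

        best, best_sse = None, np.inf
        for oc1, oc2, ow, oa1, oa2 in itertools.product(
            np.linspace(c1 - w, c1 + w, 9),
            np.linspace(c2 - w, c2 + w, 9),
            np.linspace(0.5 * w, 1.5 * w, 7),
            np.linspace(0.5, 1.5, 6),
            np.linspace(0.3, 0.9, 6),
        ):
            val = sse((oc1, oc2, ow, oa1, oa2))
            if val < best_sse:
                best_sse, best = val, (oc1, oc2, ow, oa1, oa2)
        oracle = minimize(sse, best, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-18, "maxiter": 20000}).x

        res = sq.fit_lorentzians(spec, [c1 + 0.3 * w, c2 - 0.3 * w], GREY_WINDOW)
        p1, p2 = res.peaks
        assert p1.center_ppm == pytest.approx(oracle[0], abs=0.02 * w)
        assert p2.center_ppm == pytest.approx(oracle[1], abs=0.02 * w)
        assert p1.amplitude == pytest.approx(oracle[3], rel=0.02)
        assert p2.amplitude == pytest.approx(oracle[4], rel=0.02)
        assert p1.fwhm_ppm == pytest.approx(oracle[2], rel=0.02)

    def test_noiseless_triplet_equal_integrals(self):
        spec = sq.rescale(sq.simulate_1h_spectrum(sq.AmmoniumSample(conc_14n_mM=10.0)))
        seeds = sq.detect_peaks(spec, window_ppm=GREY_WINDOW)
        res = sq.fit_lorentzians(spec, seeds, GREY_WINDOW)
        integrals = [p.integral for p in res.peaks]
        assert max(integrals) / min(integrals) - 1 < 0.005

    def test_seed_outside_window_rejected(self):
        spec = lorentzian_spectrum([(7.1, 0.01, 1.0)])
        with pytest.raises(ValueError, match="outside"):
            sq.fit_lorentzians(spec, [3.0], GREY_WINDOW)

    def test_noiseless_residual_is_negligible(self):
        spec = lorentzian_spectrum([(7.1, 0.01, 2.0)])
        res = sq.fit_lorentzians(spec, [7.1], GREY_WINDOW)
        assert res.residual_rms < 1e-8 * 2.0


class TestFitSingleLorentzian:
    def test_noise_only_window_integral_bounded_by_error(self):
        spec = flat_spectrum(sigma=0.1, seed=21)
        peak = sq.fit_single_lorentzian(spec, GREY_WINDOW)
        noise = estimate_noise(spec, (1.0, 0.0))
        err = integral_error_15n(peak, noise)
        assert abs(peak.integral) <= 3.0 * err

    def test_off_center_peak_recovered(self):
        spec = lorentzian_spectrum([(6.8, 0.012, 0.5)])
        peak = sq.fit_single_lorentzian(spec, GREY_WINDOW)
        assert peak.center_ppm == pytest.approx(6.8, abs=spec.dppm)

    def test_generator_truth_recovered_accurately(self):
        sample = sq.AmmoniumSample(conc_14n_mM=0.0, conc_15n_mM=0.12)
        spec = sq.rescale(sq.simulate_15n_spectrum(sample))
        peak = sq.fit_single_lorentzian(spec, GREY_WINDOW)
        assert peak.integral == pytest.approx(0.12, rel=1e-4)

    def test_narrow_window_rejected(self):
        spec = flat_spectrum()
        with pytest.raises(ValueError, match="10 grid points"):
            sq.fit_single_lorentzian(spec, (7.10, 7.095))


class TestNoiseEstimate:
    def test_sigma_recovered_from_gaussian_noise(self):
        spec = flat_spectrum(sigma=0.1, seed=2)
        est = estimate_noise(spec, (1.0, 0.0))
        assert est.n_points >= 200
        assert est.sigma == pytest.approx(0.1, abs=0.01)

    def test_zero_region_gives_zero_sigma(self):
        assert estimate_noise(flat_spectrum(), (1.0, 0.0)).sigma == 0.0

    def test_sigma_scales_with_intensity(self):
        spec = flat_spectrum(sigma=0.1, seed=2)
        scaled = sq.Spectrum1D(spec.params, spec.ppm, 3.0 * spec.intensity,
                               rescaled=True)
        assert estimate_noise(scaled, (1.0, 0.0)).sigma == pytest.approx(
            3.0 * estimate_noise(spec, (1.0, 0.0)).sigma)

    def test_region_overlapping_fit_window_warns(self):
        spec = flat_spectrum(sigma=0.1, seed=2)
        with pytest.warns(UserWarning, match="overlaps"):
            estimate_noise(spec, (1.0, 0.0), fit_window_ppm=(1.5, 0.5))

    def test_tiny_region_rejected(self):
        spec = flat_spectrum(n=4096)
        with pytest.raises(ValueError, match="50"):
            estimate_noise(spec, (0.05, 0.0))


class TestIntegralError:
    def test_zero_sigma_gives_zero_error(self):
        peak = sq.PeakFit(center_ppm=7.1, fwhm_ppm=0.01, amplitude=1.0,
                          integral=np.pi * 0.005)
        noise = sq.NoiseEstimate(region_ppm=(1.0, 0.0), sigma=0.0, n_points=100)
        assert integral_error_15n(peak, noise) == 0.0

    def test_error_is_sigma_times_fwhm(self):
        peak = sq.PeakFit(center_ppm=7.1, fwhm_ppm=0.01, amplitude=1.0,
                          integral=np.pi * 0.005)
        noise = sq.NoiseEstimate(region_ppm=(1.0, 0.0), sigma=0.1, n_points=100)
        assert integral_error_15n(peak, noise) == pytest.approx(0.001)

    def test_error_linear_in_injected_noise(self):
        errs = []
        for sigma in (0.05, 0.1, 0.2):
            sample = sq.AmmoniumSample(conc_14n_mM=0.0, conc_15n_mM=50.0,
                                       noise_sigma=sigma, seed=13)
            spec = sq.rescale(sq.simulate_15n_spectrum(sample))
            peak = sq.fit_single_lorentzian(spec, GREY_WINDOW)
            errs.append(integral_error_15n(peak, estimate_noise(spec, (1.0, 0.0))))
        assert errs[1] == pytest.approx(2.0 * errs[0], rel=0.15)
        assert errs[2] == pytest.approx(4.0 * errs[0], rel=0.15)


class TestLorentzianInvariants:
    def test_analytic_area_matches_numeric_over_50_fwhm(self):
        # closed-form definite integral h*(w/2)*[arctan(2x/w)] vs trapezoid
        w, h = 0.02, 1.5
        x = np.linspace(-50 * w, 50 * w, 200001)
        numeric = np.trapezoid(lorentzian(x, 0.0, w, h), x)
        analytic = h * w * np.arctan(100.0)  # = h*(w/2)*2*arctan(2*50w/w)
        assert numeric == pytest.approx(analytic, rel=0.001)
        # and the interval integral converges to the total area pi*h*w/2
        assert analytic == pytest.approx(np.pi * h * w / 2.0, rel=0.01)

    def test_fwhm_recovery_under_noise_snr50(self):
        # median relative FWHM error below 2% over repeated noisy fits
        rel_errors = []
        for seed in range(100):
            w_true = 0.012
            spec = lorentzian_spectrum([(7.1, w_true, 1.0)], sigma=1.0 / 50.0,
                                       seed=seed)
            peak = sq.fit_single_lorentzian(spec, (7.4, 6.8))
            rel_errors.append(abs(peak.fwhm_ppm - w_true) / w_true)
        assert np.median(rel_errors) < 0.02
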