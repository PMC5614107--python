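"""CTF evaluation, discretisation and whole-image correction filters."""

import numpy as np
import pytest
from scipy.optimize import brentq

from depthctf import (CtfParams, correct_image, correction_filter, ctf_image,
                      ctf_value, electron_wavelength, reweight_by_summed_ctf2,
                      strip_correct_image)


class TestElectronWavelength:
    def test_300kv_value(self):
        # independent hand evaluation of h / sqrt(2 m e V (1 + eV/2mc^2))
        assert electron_wavelength(300.0) == pytest.approx(0.0197, abs=2e-4)

    def test_100_to_300_ratio(self):
        ratio = electron_wavelength(100.0) / electron_wavelength(300.0)
        assert ratio == pytest.approx(1.88, abs=0.01)

    @pytest.mark.parametrize("kv", [80.0, 120.0, 200.0, 300.0])
    def test_monotonically_decreasing(self, kv):
        assert electron_wavelength(kv) > electron_wavelength(2 * kv) > 0

    def test_nonpositive_voltage_rejected(self):
        with pytest.raises(ValueError):
            electron_wavelength(0.0)


class TestCtfValue:
    def test_zero_frequency_gives_minus_amplitude_contrast(self, base_ctf):
        assert ctf_value(base_ctf, 0.0) == pytest.approx(-base_ctf.amplitude_contrast)

    def test_pure_amplitude_contrast_is_negative_cosine(self):
        p = CtfParams(amplitude_contrast=1.0, defocus=3000.0)
        f = np.linspace(0.0, 0.2, 50)
        lam = p.wavelength
        expected = -np.cos(np.pi * lam * f**2 * (30000.0 - 0.5 * lam**2 * f**2 * 2.7e7))
        np.testing.assert_allclose(ctf_value(p, f), expected, atol=1e-12)

    def test_first_zero_matches_root_finder(self, base_ctf):
        f0 = brentq(lambda f: float(ctf_value(base_ctf, f)), 1e-4, 0.04)
        assert abs(float(ctf_value(base_ctf, f0))) < 1e-10
        # the zero is the first one: CTF keeps one sign below it
        below = ctf_value(base_ctf, np.linspace(1e-4, f0 * 0.999, 200))
        assert np.all(below < 0)

    def test_bounded_and_azimuth_independent_without_astigmatism(self, base_ctf):
        f = np.linspace(0.0, 0.25, 100)
        v0 = ctf_value(base_ctf, f, azimuth=0.0)
        v90 = ctf_value(base_ctf, f, azimuth=90.0)
        assert np.max(np.abs(v0 - v90)) == 0.0
        assert np.all(np.abs(v0) <= 1.0 + 1e-12)

    def test_astigmatic_defocus_along_axes(self):
        p = CtfParams(defocus=3000.0, defocus_delta=200.0, astig_angle=30.0)
        f = 0.05
        on_axis = ctf_value(p, f, azimuth=30.0)
        off_axis = ctf_value(p, f, azimuth=120.0)
        assert on_axis == pytest.approx(float(ctf_value(
            CtfParams(defocus=3200.0), f)), abs=1e-12)
        assert off_axis == pytest.approx(float(ctf_value(
            CtfParams(defocus=2800.0), f)), abs=1e-12)

    def test_negative_frequency_rejected(self, base_ctf):
        with pytest.raises(ValueError):
            ctf_value(base_ctf, -0.1)


class TestCtfImage:
    @pytest.mark.parametrize("shape", [(16, 16), (15, 17), (1, 32)])
    def test_origin_is_minus_amplitude_contrast(self, base_ctf, shape):
        grid = ctf_image(base_ctf, shape, pixel_size=5.0)
        assert grid[0, 0] == pytest.approx(-base_ctf.amplitude_contrast)

    def test_nyquist_sample_along_x(self, base_ctf):
        grid = ctf_image(base_ctf, (8, 16), pixel_size=4.0)
        expected = float(ctf_value(base_ctf, 1.0 / (2 * 4.0), azimuth=0.0))
        assert grid[0, 8] == pytest.approx(expected, abs=1e-12)

    def test_even_under_point_reflection(self, base_ctf):
        p = CtfParams(defocus=3000.0, defocus_delta=300.0, astig_angle=20.0)
        g = ctf_image(p, (12, 18), pixel_size=5.0)
        flipped = np.roll(g[::-1, ::-1], shift=(1, 1), axis=(0, 1))
        np.testing.assert_allclose(g, flipped, atol=1e-12)


class TestCorrectionFilter:
    def test_phaseflip_is_pure_signs_with_positive_zero(self):
        g = np.array([[0.5, -0.2], [0.0, -0.9]])
        filt = correction_filter(g, "phaseflip")
        np.testing.assert_array_equal(filt, [[1.0, -1.0], [1.0, -1.0]])

    def test_multiply_returns_ctf_itself(self, base_ctf):
        g = ctf_image(base_ctf, (8, 8), pixel_size=5.0)
        np.testing.assert_array_equal(correction_filter(g, "multiply"), g)
        assert correction_filter(g, "multiply")[0, 0] == pytest.approx(-0.07)

    def test_wiener_approaches_inverse_ctf_for_small_constant(self):
        g = np.full((4, 4), 0.5)
        filt = correction_filter(g, "wiener", wiener_constant=1e-9)
        np.testing.assert_allclose(filt, 1.0 / g, rtol=1e-8)

    def test_unknown_mode_and_bad_wiener_constant(self):
        with pytest.raises(ValueError):
            correction_filter(np.ones((2, 2)), "deconvolve")
        with pytest.raises(ValueError):
            correction_filter(np.ones((2, 2)), "wiener", wiener_constant=0.0)


class TestCorrectImage:
    def test_constant_image_phaseflip_flips_sign(self, base_ctf):
        img = np.full((16, 16), 3.5)
        out = correct_image(img, base_ctf, "phaseflip")
        np.testing.assert_allclose(out, -img, atol=1e-12)

    def test_phaseflip_twice_restores_image(self, base_ctf, rng):
        img = rng.normal(size=(24, 32))
        twice = correct_image(correct_image(img, base_ctf, "phaseflip"),
                              base_ctf, "phaseflip")
        np.testing.assert_allclose(twice, img, atol=1e-12)

    def test_delta_image_multiply_gives_filter_psf(self, base_ctf):
        img = np.zeros((16, 16))
        img[0, 0] = 1.0
        out = correct_image(img, base_ctf, "multiply")
        psf = np.fft.ifft2(ctf_image(base_ctf, (16, 16))).real
        np.testing.assert_allclose(out, psf, atol=1e-12)

    def test_multiply_then_divide_recovers_spectrum(self, base_ctf, rng):
        img = rng.normal(size=(16, 16))
        grid = ctf_image(base_ctf, img.shape)
        out = correct_image(img, base_ctf, "multiply")
        away = np.abs(grid) > 0.1
        recovered = np.fft.fft2(out)[away] / grid[away]
        np.testing.assert_allclose(recovered, np.fft.fft2(img)[away], atol=1e-9)

    def test_linearity(self, base_ctf, rng):
        a, b = rng.normal(size=(2, 12, 12))
        lhs = correct_image(2.0 * a - 3.0 * b, base_ctf, "multiply")
        rhs = 2.0 * correct_image(a, base_ctf, "multiply") \
            - 3.0 * correct_image(b, base_ctf, "multiply")
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_nonfinite_pixels_rejected(self, base_ctf):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            correct_image(img, base_ctf, "phaseflip")


class TestStripCorrectImage:
    def test_untilted_equals_whole_image_correction(self, rng):
        p = CtfParams(defocus=3000.0, pixel_size=10.0)
        img = rng.normal(size=(16, 32))
        out = strip_correct_image(img, p, tilt_angle=0.0, strip_width=8)
        np.testing.assert_allclose(out, correct_image(img, p, "phaseflip"),
                                   atol=1e-12)

    def test_full_width_strip_equals_whole_image_correction(self, rng):
        p = CtfParams(defocus=3000.0, pixel_size=10.0)
        img = rng.normal(size=(16, 32))
        out = strip_correct_image(img, p, tilt_angle=45.0, strip_width=32)
        np.testing.assert_allclose(out, correct_image(img, p, "phaseflip"),
                                   atol=1e-12)

    def test_opposite_edges_corrected_at_their_local_defocus(self):
        # two point sources at opposite x extremes of a 60-degree image: the
        # multiply-corrected response around each point must match the
        # whole-image response at that point's local defocus.
        p = CtfParams(defocus=4000.0, pixel_size=10.0)
        nx, w = 256, 64
        img = np.zeros((4, nx))
        cols = [40, nx - 40]
        img[2, cols[0]] = 1.0
        img[2, cols[1]] = 1.0
        out = strip_correct_image(img, p, tilt_angle=60.0, strip_width=w,
                                  mode="multiply")
        nm_per_col = p.pixel_size * np.sin(np.deg2rad(60.0)) * 0.1
        for col in cols:
            local = CtfParams(defocus=p.defocus + (col - nx // 2) * nm_per_col,
                              pixel_size=10.0)
            single = np.zeros((4, nx))
            single[2, col] = 1.0
            ref = correct_image(single, local, "multiply")
            sl = slice(col - 10, col + 11)
            np.testing.assert_allclose(out[2, sl], ref[2, sl], atol=5e-3)

    def test_oversized_strip_rejected(self):
        with pytest.raises(ValueError):
            strip_correct_image(np.zeros((4, 16)), CtfParams(), 10.0,
                                strip_width=32)


class TestReweightBySummedCtf2:
    def test_single_ctf_roundtrip_away_from_floor(self, rng):
        p = CtfParams(defocus=3000.0, pixel_size=5.0)
        x = rng.normal(size=(16, 16, 16))
        # forward-modulate by CTF^2, then reweight back
        freqs = [np.fft.fftfreq(16, d=5.0)] * 3
        gz, gy, gx = np.meshgrid(*freqs, indexing="ij", sparse=True)
        f = np.sqrt(gz**2 + gy**2 + gx**2)
        g2 = np.asarray(ctf_value(p, f)) ** 2
        modulated = np.fft.ifftn(np.fft.fftn(x) * g2).real
        out = reweight_by_summed_ctf2(modulated, [p], pixel_size=5.0)
        mask = g2 > 1e-3 * g2.max()
        np.testing.assert_allclose(np.fft.fftn(out)[mask], np.fft.fftn(x)[mask],
                                   atol=1e-8)

    def test_scale_consistent_for_identical_ctfs(self, rng):
        p = CtfParams(defocus=3000.0, pixel_size=5.0)
        x = rng.normal(size=(12, 12, 12))
        one = reweight_by_summed_ctf2(x, [p], pixel_size=5.0)
        two = reweight_by_summed_ctf2(x, [p, p], pixel_size=5.0)
        np.testing.assert_allclose(two, one / 2.0, atol=1e-10)

    def test_interleaved_zero_ensemble_stays_finite(self, rng):
        # defoci chosen so the summed CTF^2 has no common zeros below Nyquist
        ps = [CtfParams(defocus=d, pixel_size=5.0) for d in (2000.0, 3100.0, 4700.0)]
        x = rng.normal(size=(24, 24, 24))
        out = reweight_by_summed_ctf2(x, ps, pixel_size=5.0)
        assert np.all(np.isfinite(out))

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            reweight_by_summed_ctf2(np.zeros((4, 4, 4)), [], pixel_size=5.0)
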