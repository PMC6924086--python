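"""Fourier fringe displacement estimation on pseudo-speckle pairs."""

import numpy as np
import pytest

from spinetrack import (
    FringeEstimate,
    NoFringesError,
    ParameterError,
    SpeckleSpec,
    SpectrumImage,
    displacement_from_fringes,
    estimate_fringes,
    gen_speckle,
    measure_displacement,
    power_spectrum,
    resolve_sign,
    shift_image,
    sum_frames,
)


def speckle(seed=0, n=256):
    return gen_speckle(SpeckleSpec(size_px=n, sigma=50, seed=seed))


class TestSumFrames:
    def test_identical_frames_double_the_centered_signal(self):
        f = speckle(0, 64)
        out = sum_frames(f, f)
        np.testing.assert_allclose(out.pixels, 2 * (f.pixels - f.pixels.mean()), atol=1e-9)

    def test_opposite_frames_cancel(self):
        f = speckle(1, 64)
        centered = f.pixels - f.pixels.mean()
        out = sum_frames(centered, -centered)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        b = rng.uniform(0, 255, (32, 32))
        out = sum_frames(a, b)
        np.testing.assert_allclose(out.pixels, (a - a.mean()) + (b - b.mean()), atol=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            sum_frames(np.zeros((32, 32)), np.zeros((32, 16)))


class TestPowerSpectrum:
    def test_constant_image_all_zero_after_dc_suppression(self):
        spec = power_spectrum(np.full((32, 32), 9.0))
        assert np.all(spec.power <= 1e-18)

    def test_pure_cosine_gives_symmetric_peak_pair(self):
        n, k = 64, 9
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        img = np.tile(x, (n, 1)) * 100
        spec = power_spectrum(img, window="none", dc_suppress_radius=0)
        c = n // 2
        p = spec.power
        top2 = np.argsort(p.ravel())[-2:]
        peaks = {tuple(np.unravel_index(i, p.shape)) for i in top2}
        assert peaks == {(c, c + k), (c, c - k)}

    def test_parseval_energy_identity(self, rng):
        n = 64
        img = rng.uniform(0, 255, (n, n))
        spec = power_spectrum(img, window="hann", dc_suppress_radius=0)
        w = np.outer(np.hanning(n), np.hanning(n))
        x = (img - np.sum(img * w) / np.sum(w)) * w
        assert spec.power.sum() == pytest.approx(n**2 * np.sum(x**2), rel=1e-6)

    def test_point_symmetry_for_real_input(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        p = power_spectrum(img, dc_suppress_radius=0).power
        # real input: F(-k) = conj(F(k)), so power is point-symmetric about DC
        flipped = p[::-1, ::-1]
        sym = np.roll(np.roll(flipped, 1, axis=0), 1, axis=1)  # even-size center fix
        np.testing.assert_allclose(p, sym, rtol=1e-9, atol=1e-6 * p.max())

    def test_non_square_rejected(self):
        with pytest.raises(ParameterError):
            power_spectrum(np.zeros((32, 64)))


def analytic_fringe_spectrum(n: int, dx: float, dy: float) -> SpectrumImage:
    """Power spectrum carrying the ideal cos^2 fringe system of a shift (dx, dy)."""
    c = n // 2
    s, xi = np.meshgrid(np.arange(n) - c, np.arange(n) - c)
    p = np.cos(np.pi * (s * dx + xi * dy) / n) ** 2
    r2 = s**2 + xi**2
    p[r2 <= 4] = 0.0
    return SpectrumImage(power=p, n=n)


class TestEstimateFringes:
    def test_axis_aligned_fringes_period_and_pitch(self):
        spec = analytic_fringe_spectrum(256, 8.0, 0.0)
        fr = estimate_fringes(spec)
        assert fr.period_bins == pytest.approx(32.0, abs=0.5)
        assert fr.pitch_deg == pytest.approx(90.0, abs=2.0)

    def test_diagonal_fringes_pitch_45(self):
        d = 8.0 / np.sqrt(2.0)
        spec = analytic_fringe_spectrum(256, d, -d)  # shift toward -45 deg -> strips at +45
        fr = estimate_fringes(spec)
        assert fr.pitch_deg == pytest.approx(45.0, abs=2.0)

    def test_unshifted_pair_reports_no_fringes(self):
        f = speckle(5)
        spec = power_spectrum(sum_frames(f, f))
        with pytest.raises(NoFringesError):
            estimate_fringes(spec)

    def test_rotating_shift_by_90_rotates_pitch_by_90(self):
        fr_x = estimate_fringes(analytic_fringe_spectrum(256, 10.0, 0.0))
        fr_y = estimate_fringes(analytic_fringe_spectrum(256, 0.0, 10.0))
        assert abs((fr_x.pitch_deg - fr_y.pitch_deg) % 180) == pytest.approx(90.0, abs=2.0)


class TestDisplacementFromFringes:
    def test_magnitude_is_n_over_period(self):
        fr = FringeEstimate(period_bins=32.0, pitch_deg=90.0, contrast=0.5)
        d = displacement_from_fringes(fr, 256)
        assert d.magnitude_px == pytest.approx(8.0)
        assert d.direction_deg == pytest.approx(0.0)
        assert not d.sign_resolved

    def test_no_fringes_maps_to_zero(self):
        d = displacement_from_fringes(None, 256)
        assert d.magnitude_px == 0.0
        assert d.sign_resolved

    def test_pitch_90_means_shift_along_x(self):
        fr = FringeEstimate(period_bins=16.0, pitch_deg=90.0, contrast=0.5)
        assert displacement_from_fringes(fr, 256).direction_deg == pytest.approx(0.0)


class TestResolveSign:
    def test_positive_x_shift_resolves_to_0_not_180(self):
        f1 = speckle(8)
        f2 = shift_image(f1, 8.0, 0.0)
        d = measure_displacement(f1, f2)
        assert d.sign_resolved
        assert min(d.direction_deg, 360 - d.direction_deg) < 3.0

    def test_negative_y_shift_resolves_to_270(self):
        f1 = speckle(9)
        f2 = shift_image(f1, 0.0, -5.0)
        d = measure_displacement(f1, f2)
        assert d.sign_resolved
        assert d.direction_deg == pytest.approx(270.0, abs=3.0)

    def test_zero_magnitude_returned_unchanged(self):
        from spinetrack import DisplacementVector

        f1 = speckle(10, 64)
        d0 = DisplacementVector(0.0, 0.0, sign_resolved=False)
        out = resolve_sign(f1, f1, d0)
        assert out.magnitude_px == 0.0
        assert out.sign_resolved


class TestMeasureDisplacement:
    @pytest.mark.parametrize(
        "dx, dy, mag", [(6.0, 0.0, 6.0), (4.0, 4.0, np.sqrt(32.0))]
    )
    def test_known_shift_recovered(self, dx, dy, mag):
        f1 = speckle(12)
        f2 = shift_image(f1, dx, dy)
        d = measure_displacement(f1, f2)
        assert d.magnitude_px == pytest.approx(mag, abs=0.5)
        true_dir = np.degrees(np.arctan2(dy, dx)) % 360
        ang_err = abs((d.direction_deg - true_dir + 180) % 360 - 180)
        assert ang_err < 3.0

    def test_zero_shift_takes_no_fringe_path(self):
        f1 = speckle(13)
        d = measure_displacement(f1, f1)
        assert d.magnitude_px == 0.0

    def test_mm_scale_applied(self):
        from spinetrack import SpeckleConfig

        f1 = speckle(14)
        f2 = shift_image(f1, 6.0, 0.0)
        d = measure_displacement(f1, f2, SpeckleConfig(mm_per_px=0.1))
        assert d.magnitude_mm == pytest.approx(d.magnitude_px * 0.1)
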