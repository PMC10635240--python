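"""Sigma extraction, calibration, and the Sigma -> D inversion."""

import numpy as np
import pytest

from chromascan import (
    SigmaMap,
    SpectralCube,
    build_calibration,
    compute_sigma,
    estimate_d_map,
    generate_cube,
    normalize_cube,
)


def _cube_from_spectra(spectra, reference=None):
    spectra = np.asarray(spectra, float)
    n_lam = spectra.shape[-1]
    lam = 500.0 + 2.0 * np.arange(n_lam)
    return SpectralCube(intensities=spectra, wavelengths=lam, reference=reference)


class TestNormalizeCube:
    def test_reference_equals_cube_normalizes_to_one(self):
        ref = np.array([2.0, 4.0, 8.0])
        cube = _cube_from_spectra(np.tile(ref, (2, 2, 1)), reference=ref)
        norm = normalize_cube(cube)
        assert np.allclose(norm.intensities, 1.0)
        assert np.allclose(norm.reference, 1.0)

    def test_double_reference_gives_constant_two(self):
        ref = np.array([3.0, 5.0, 7.0])
        spectra = np.ones((1, 1, 3)) * ref * 2.0
        norm = normalize_cube(_cube_from_spectra(spectra, reference=ref))
        assert np.allclose(norm.intensities[0, 0], 2.0)

    def test_zero_reference_rejected(self):
        cube = _cube_from_spectra(np.ones((1, 1, 3)), reference=np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            normalize_cube(cube)


class TestComputeSigma:
    def test_constant_spectrum_zero_sigma(self):
        cube = _cube_from_spectra(np.ones((2, 2, 4)))
        sigma = compute_sigma(cube, np.ones((2, 2), bool))
        assert np.allclose(sigma.values, 0.0)

    def test_two_point_spectrum_sample_sd(self):
        """[1, 3] -> sqrt(((1-2)^2 + (3-2)^2) / (2-1)) = sqrt(2)."""
        cube = _cube_from_spectra(np.array([[[1.0, 3.0]]]))
        sigma = compute_sigma(cube, np.ones((1, 1), bool))
        assert sigma.values[0, 0] == pytest.approx(1.4142, abs=1e-4)

    def test_mean_shift_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(1.0, 0.05, size=(3, 3, 50))
        shifted = base + 0.7
        m = np.ones((3, 3), bool)
        s1 = compute_sigma(_cube_from_spectra(base), m)
        s2 = compute_sigma(_cube_from_spectra(shifted), m)
        assert np.allclose(s1.values, s2.values)

    def test_iid_noise_expectation(self):
        """Sample SD of i.i.d. N(1, 0.05) spectra concentrates near 0.05."""
        rng = np.random.default_rng(11)
        spectra = rng.normal(1.0, 0.05, size=(100, 100, 101))
        sigma = compute_sigma(_cube_from_spectra(spectra), np.ones((100, 100), bool))
        assert sigma.values.mean() == pytest.approx(0.05, abs=0.002)

    def test_noise_floor_subtraction(self):
        rng = np.random.default_rng(4)
        spectra = rng.normal(1.0, 0.05, size=(60, 60, 101))
        m = np.ones((60, 60), bool)
        sigma = compute_sigma(_cube_from_spectra(spectra), m, noise_floor=0.03)
        assert sigma.values.mean() == pytest.approx(np.sqrt(0.05**2 - 0.03**2), abs=0.003)

    def test_too_few_wavelengths(self):
        cube = SpectralCube(np.ones((1, 1, 1)), np.array([500.0]))
        with pytest.raises(ValueError):
            compute_sigma(cube, np.ones((1, 1), bool))


class TestCalibration:
    def test_knots_strictly_increasing(self, instrument):
        cal = build_calibration(instrument, 0.35, 200_000.0, np.arange(2.1, 2.91, 0.1))
        assert cal.d_knots.size == 9
        assert np.all(np.diff(cal.sigma_knots) > 0)

    def test_rebuild_is_identical(self, instrument):
        grid = np.arange(2.1, 2.91, 0.1)
        a = build_calibration(instrument, 0.35, 200_000.0, grid)
        b = build_calibration(instrument, 0.35, 200_000.0, grid)
        assert np.array_equal(a.sigma_knots, b.sigma_knots)

    def test_single_knot_rejected(self, instrument):
        with pytest.raises(ValueError):
            build_calibration(instrument, 0.35, 200_000.0, np.array([2.5]))


class TestEstimateDMap:
    def test_knot_sigma_returns_knot_d(self, calibration):
        i = len(calibration.sigma_knots) // 2
        sigma = SigmaMap(np.full((1, 1), calibration.sigma_knots[i]), np.ones((1, 1), bool))
        dmap = estimate_d_map(sigma, calibration)
        assert dmap.values[0, 0] == pytest.approx(calibration.d_knots[i])
        assert not dmap.out_of_range_flags.any()

    def test_zero_sigma_clips_low_and_flags(self, calibration):
        sigma = SigmaMap(np.zeros((1, 1)), np.ones((1, 1), bool))
        dmap = estimate_d_map(sigma, calibration)
        assert dmap.values[0, 0] == pytest.approx(calibration.d_knots[0])
        assert dmap.out_of_range_flags[0, 0]

    def test_monotone_in_sigma(self, calibration):
        grid = np.linspace(0.0, calibration.sigma_knots[-1] * 1.2, 200).reshape(1, -1)
        dmap = estimate_d_map(SigmaMap(grid, np.ones_like(grid, dtype=bool)), calibration)
        assert np.all(np.diff(dmap.values[0]) >= 0)

    def test_noise_free_round_trip(self, chromatin, instrument, ri, calibration):
        """generate_cube -> compute_sigma -> estimate_d_map at true D = 2.6."""
        mask = np.ones((10, 10), bool)
        cube = generate_cube(np.full((10, 10), 2.6), mask, chromatin, instrument, ri, seed=2)
        sigma = compute_sigma(normalize_cube(cube), mask)
        dmap = estimate_d_map(sigma, calibration)
        assert np.nanmean(dmap.values[mask]) == pytest.approx(2.60, abs=0.02)

    def test_reference_only_pixels_have_zero_sigma(self, chromatin, instrument, ri):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        cube = generate_cube(np.full((4, 4), 2.5), mask, chromatin, instrument, ri, seed=0)
        sigma = compute_sigma(normalize_cube(cube), ~mask)
        assert np.all(sigma.values[~mask] == 0.0)


class TestParameterRecovery:
    @pytest.mark.parametrize("d_true", [2.2, 2.4, 2.6, 2.8])
    def test_noisy_recovery_within_tolerance(self, d_true, chromatin, instrument, ri, calibration):
        """Spectral noise SD 0.02, 64 pixels: nucleus-mean D within 0.05."""
        mask = np.ones((8, 8), bool)
        cube = generate_cube(
            np.full((8, 8), d_true), mask, chromatin, instrument, ri,
            noise_sd=0.02, seed=int(d_true * 100),
        )
        sigma = compute_sigma(normalize_cube(cube), mask, noise_floor=0.02)
        dmap = estimate_d_map(sigma, calibration)
        good = dmap.mask & ~dmap.out_of_range_flags
        assert dmap.values[good].mean() == pytest.approx(d_true, abs=0.05)
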