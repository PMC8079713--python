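"""Line-profile measurements: tilted-circle diameter, super-Gaussian
thickness, septal density."""

import math

import numpy as np
import pytest

from vercini import (LineProfile, ParameterError, extract_septal_profiles,
                     fit_super_gaussian, fit_tilted_circle, septal_density,
                     super_gaussian_fwhm, tilted_circle_profile,
                     total_septal_intensity)


def super_gaussian(x, x0, sigma, p, amp=1.0, baseline=0.0):
    return amp * np.exp(-(((x - x0) ** 2) / (2 * sigma**2)) ** p) + baseline


class TestExtractProfiles:
    def test_zero_rotation_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((21, 25))
        lat, ax = extract_septal_profiles(img, (12.0, 10.0), 0.0,
                                          pixel_size_nm=65.0)
        assert np.allclose(lat.intensities, img[8:13, :].mean(axis=0))
        assert np.allclose(ax.intensities, img[:, 10:15].mean(axis=1))

    def test_averaging_band_is_five_rows(self):
        img = np.zeros((21, 25))
        img[8:13, :] = 10.0   # exactly the +/-2 px band around row 10
        img[7, :] = 1000.0    # just outside: must not contribute
        img[13, :] = 1000.0
        lat, _ = extract_septal_profiles(img, (12.0, 10.0), 0.0)
        assert np.allclose(lat.intensities, 10.0)

    def test_axis_aligned_bar_cross_section(self):
        img = np.zeros((31, 31))
        img[:, 13:18] = 50.0  # vertical bar of width 5
        lat, _ = extract_septal_profiles(img, (15.0, 15.0), 0.0)
        assert lat.intensities.max() == pytest.approx(50.0, rel=0.01)
        assert lat.intensities[lat.positions_nm == 0.0][0] == 50.0

    def test_rotated_bar_recovered(self):
        # bar at 30 degrees to the x axis; after rotation the lateral
        # profile must show the same cross-section as an axis-aligned bar
        yy, xx = np.mgrid[0:41, 0:41]
        theta = math.radians(30.0)
        # distance from the line through (20, 20) at angle theta
        d = -(xx - 20) * math.sin(theta) + (yy - 20) * math.cos(theta)
        img = np.where(np.abs(d) < 3.0, 80.0, 0.0).astype(float)
        lat, ax = extract_septal_profiles(img, (20.0, 20.0), 30.0)
        assert ax.intensities.max() == pytest.approx(80.0, rel=0.05)
        ax_above = ax.positions_nm[ax.intensities > 40.0]
        assert ax_above[-1] - ax_above[0] == pytest.approx(6 * 65.0, abs=130)

    def test_intensity_scaling_linearity(self):
        rng = np.random.default_rng(1)
        img = rng.random((21, 21))
        lat1, _ = extract_septal_profiles(img, (10.0, 10.0), 0.0)
        lat2, _ = extract_septal_profiles(5.0 * img, (10.0, 10.0), 0.0)
        assert np.allclose(lat2.intensities, 5.0 * lat1.intensities)

    def test_band_outside_image_rejected(self):
        with pytest.raises(ParameterError):
            extract_septal_profiles(np.zeros((21, 21)), (10.0, 1.0), 0.0)


class TestTiltedCircle:
    def test_projection_mass_conserved_for_any_diameter(self):
        pos = np.arange(-1500.0, 1501.0, 25.0)
        for d in (400.0, 1100.0, 1800.0):
            prof = tilted_circle_profile(pos, d, 0.0, 5000.0, 120.0, 0.0)
            assert prof.sum() == pytest.approx(5000.0, rel=1e-3)

    def test_diameter_recovery_noiseless(self):
        pos = np.arange(-900.0, 901.0, 32.5)
        model = tilted_circle_profile(pos, 1100.0, 0.0, 5000.0, 120.0, 1.0)
        fit = fit_tilted_circle(LineProfile(pos, model, "lateral"))
        assert fit.d_nm == pytest.approx(1100.0, rel=0.01)
        assert fit.converged

    def test_rim_peaks_approach_diameter_as_psf_shrinks(self):
        pos = np.arange(-900.0, 901.0, 10.0)
        prof = tilted_circle_profile(pos, 1100.0, 0.0, 5000.0, 15.0, 0.0)
        peaks = []
        for half in (pos < 0, pos > 0):
            peaks.append(pos[half][np.argmax(prof[half])])
        assert peaks[1] - peaks[0] == pytest.approx(1100.0, abs=2 * 10.0)

    def test_fixed_psf_mode(self):
        pos = np.arange(-900.0, 901.0, 32.5)
        model = tilted_circle_profile(pos, 1000.0, 30.0, 4000.0, 120.0, 0.5)
        fit = fit_tilted_circle(LineProfile(pos, model, "lateral"),
                                psf_sigma_nm=120.0)
        assert fit.psf_sigma_nm == 120.0
        assert fit.d_nm == pytest.approx(1000.0, rel=0.01)


class TestSuperGaussian:
    def test_gaussian_special_case_fwhm(self):
        assert super_gaussian_fwhm(100.0, 1.0) == pytest.approx(235.48,
                                                                abs=0.01)

    def test_p2_fwhm_closed_form(self):
        x = np.arange(-600.0, 601.0, 20.0)
        prof = LineProfile(x, super_gaussian(x, 10.0, 150.0, 2.0, 2.0, 0.5),
                           "axial")
        fit = fit_super_gaussian(prof)
        expected = 2 * math.sqrt(2) * 150.0 * math.log(2) ** 0.25
        assert expected == pytest.approx(387.1, abs=0.1)
        assert fit.fwhm_nm == pytest.approx(expected, rel=0.005)

    def test_fwhm_monotone_in_sigma(self):
        fwhms = [super_gaussian_fwhm(s, 1.7) for s in (50, 100, 200, 400)]
        assert all(a < b for a, b in zip(fwhms, fwhms[1:]))

    def test_fix_p_reduces_to_gaussian_fit(self):
        x = np.arange(-600.0, 601.0, 20.0)
        y = super_gaussian(x, -25.0, 120.0, 1.0, 3.0, 0.2)
        fit = fit_super_gaussian(LineProfile(x, y, "axial"), fix_p=1.0)
        assert fit.p == 1.0
        assert fit.sigma_nm == pytest.approx(120.0, rel=1e-4)
        assert fit.fwhm_nm == pytest.approx(2.3548 * 120.0, rel=1e-3)


class TestSeptalDensity:
    def test_zero_intensity(self):
        assert septal_density(0.0, 1100.0) == 0.0

    def test_circumference_normalisation(self):
        assert septal_density(3455.8, 1100.0) == pytest.approx(1.0, abs=1e-4)

    def test_total_intensity_is_baseline_subtracted_sum(self):
        x = np.arange(-400.0, 401.0, 50.0)
        prof = LineProfile(x, np.full(x.size, 2.0), "lateral")
        assert total_septal_intensity(prof) == 0.0
        prof2 = LineProfile(x, np.concatenate([[2.0], np.full(x.size - 1,
                                                              7.0)]),
                            "lateral")
        assert total_septal_intensity(prof2) == 5.0 * (x.size - 1)
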