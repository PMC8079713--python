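"""Synthetic-data generator: filament process, rendering and noise model."""

import math

import numpy as np
import pytest

from vercini import (BackgroundParams, ParameterError, SimConfig,
                     add_camera_noise, constant_speed, render_frame,
                     sample_filament_count, simulate_constriction_trace,
                     simulate_filaments, simulate_ring_movie,
                     simulate_thickness_trace)


class TestFilamentCount:
    def test_zero_density_always_zero(self, rng):
        assert all(sample_filament_count(0.0, rng) == 0 for _ in range(100))

    @pytest.mark.parametrize("density", [1.3, 3.3, 6.5, 37.5])
    def test_mean_matches_density(self, density, rng):
        draws = np.array([sample_filament_count(density, rng)
                          for _ in range(100_000)])
        se = math.sqrt(density / draws.size)
        assert abs(draws.mean() - density) < 3 * se

    def test_variance_equals_mean(self, rng):
        draws = np.array([sample_filament_count(3.3, rng)
                          for _ in range(100_000)])
        assert 0.95 < draws.var() / draws.mean() < 1.05

    def test_negative_density_rejected(self, rng):
        with pytest.raises(ParameterError):
            sample_filament_count(-1.0, rng)


class TestFilamentProcess:
    def test_all_immobile_when_fraction_one(self, rng):
        cfg = SimConfig(immobile_fraction=1.0, seed=1)
        fils = simulate_filaments(cfg, rng)
        assert fils and all(f.immobile and f.speed < 10.0 for f in fils)

    def test_constant_sampler_gives_exact_speed(self, rng):
        cfg = SimConfig(immobile_fraction=0.0,
                        speed_sampler=constant_speed(30.0), seed=1)
        fils = simulate_filaments(cfg, rng)
        assert fils and all(f.speed == 30.0 for f in fils)

    def test_steady_state_count(self, rng):
        cfg = SimConfig(filament_density=3.3, mean_lifetime_s=30.0,
                        n_frames=10_000, seed=1)
        fils = simulate_filaments(cfg, rng)
        times = np.arange(10_000, dtype=float)
        births = np.array([f.birth_time for f in fils])
        deaths = np.array([f.death_time for f in fils])
        counts = ((births[None, :] <= times[:, None])
                  & (times[:, None] < deaths[None, :])).sum(axis=1)
        assert abs(counts.mean() - 3.3) / 3.3 < 0.05

    def test_angle_advances_with_direction(self):
        from vercini import GroundTruthFilament

        f = GroundTruthFilament(0.0, 100.0, 0.0, 55.0, -1, False)
        # 55 nm/s on a 550 nm radius = 0.1 rad/s, clockwise
        assert f.angle_at(10.0, 550.0) == pytest.approx(
            (-math.degrees(1.0)) % 360.0)


class TestRendering:
    def test_background_value_at_centre(self):
        bg = BackgroundParams(a=30.0, sigma1_px=6.0, b=20.0, sigma2_px=10.0,
                              c=2.0)
        img = render_frame((33, 33), (16, 16), 8.0, [], 1000.0, 2.0, bg)
        assert img[16, 16] == pytest.approx(30 + 20 + 2)

    def test_background_far_field_approaches_constant_term(self):
        bg = BackgroundParams(a=30.0, sigma1_px=2.0, b=0.5, sigma2_px=1.5,
                              c=2.0)
        # r = 10 * max width = 20 px from the centre; the Gaussian term is
        # gone and the slow Cauchy tail (b/101) is below 1% of c
        img = render_frame((9, 45), (2.0, 4.0), 1.0, [], 1000.0, 2.0, bg)
        assert img[4, 24] == pytest.approx(2.0, rel=0.01)

    def test_photon_conservation_single_filament(self):
        img = render_frame((41, 41), (20, 20), 8.0, [137.0], 2000.0, 2.0,
                           None)
        assert img.sum() == pytest.approx(2000.0, rel=1e-3)

    def test_photon_conservation_many_filaments(self):
        angles = [0.0, 45.0, 133.0, 290.0]
        img = render_frame((61, 61), (30, 30), 8.0, angles, 1500.0, 2.0, None)
        assert img.sum() == pytest.approx(1500.0 * len(angles), rel=1e-3)

    def test_invalid_psf_rejected(self):
        with pytest.raises(ParameterError):
            render_frame((9, 9), (4, 4), 2.0, [], 100.0, 0.0, None)


class TestCameraNoise:
    def test_zero_photons_zero_read_noise_is_offset(self, rng):
        out = add_camera_noise(np.zeros((10, 10)), 2.0, 0.0, 100.0, rng)
        assert np.all(out == 100.0)

    def test_variance_is_gain_sq_mean_plus_read_noise_sq(self, rng):
        out = add_camera_noise(np.full(100_000, 100.0), 2.0, 3.0, 100.0, rng)
        expected = 100 * 2**2 + 3**2
        assert abs(out.var() / expected - 1) < 0.05

    def test_mean_preserved_at_unit_gain(self, rng):
        out = add_camera_noise(np.full(100_000, 100.0), 1.0, 0.0, 50.0, rng)
        se = math.sqrt(100.0 / out.size)
        assert abs(out.mean() - 150.0) < 3 * se

    def test_negative_expectation_rejected(self, rng):
        with pytest.raises(ParameterError):
            add_camera_noise(np.array([-1.0]), 2.0, 3.0, 100.0, rng)


class TestRingMovie:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=7, n_frames=10)
        (s1, f1), (s2, f2) = simulate_ring_movie(cfg), simulate_ring_movie(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert f1 == f2

    def test_movie_shape_and_metadata(self):
        cfg = SimConfig(seed=3, n_frames=5)
        stack, _ = simulate_ring_movie(cfg)
        assert len(stack) == 5
        assert stack.pixel_size_nm == 65.0
        assert np.all(stack.frames >= 0)


class TestConstrictionTrace:
    def test_noiseless_flat_before_t0(self):
        tr = simulate_constriction_trace(1100, 300, 1000, 0.0, 10.0, 100)
        assert np.all(tr.diameter[tr.t < 300] == 1100.0)

    def test_noiseless_half_area_point(self):
        d0, t0, k = 1100.0, 0.0, 1000.0
        t_half = t0 + math.pi * d0**2 / (8 * k)
        tr = simulate_constriction_trace(d0, t0, k, 0.0, t_half, 3)
        assert tr.diameter[1] == pytest.approx(d0 / math.sqrt(2))

    def test_noiseless_completion_time(self):
        d0, t0, k, dt = 1100.0, 100.0, 1000.0, 5.0
        tr = simulate_constriction_trace(d0, t0, k, 0.0, dt, 300)
        t_zero = tr.t[np.nonzero(tr.diameter == 0)[0][0]]
        assert abs(t_zero - (t0 + math.pi * d0**2 / (4 * k))) <= dt

    def test_ground_truth_recorded(self):
        tr = simulate_constriction_trace(900, 50, 800, 10.0, 1.0, 20,
                                         np.random.default_rng(0))
        assert tr.ground_truth == {"d0": 900, "t0": 50, "k": 800}


class TestThicknessTrace:
    def test_single_state_mean(self, rng):
        x = simulate_thickness_trace(600, 80, 330, 30, step_index=500, n=500,
                                     rng=rng)
        assert abs(x.mean() - 600) < 3 * 80 / math.sqrt(500)

    def test_two_segments_have_stated_moments(self, rng):
        x = simulate_thickness_trace(600, 80, 330, 30, step_index=2000,
                                     n=4000, rng=rng)
        pre, post = x[:2000], x[2000:]
        assert abs(pre.mean() - 600) < 3 * 80 / math.sqrt(2000)
        assert abs(post.mean() - 330) < 3 * 30 / math.sqrt(2000)

    def test_bad_step_index_rejected(self, rng):
        with pytest.raises(ParameterError):
            simulate_thickness_trace(600, 80, 330, 30, step_index=11, n=10,
                                     rng=rng)
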