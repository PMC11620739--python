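"""Autocorrelogram-based hexagonality metrics on analytic and noise maps."""

import numpy as np
import pytest

from flexgrid.fixtures import (grid_kernel, ideal_grid_population,
                               pixel_coordinates)
from flexgrid.gridmetrics import (compute_angular_spread,
                                  compute_autocorrelogram, compute_gridness,
                                  detect_maxima, estimate_spacing,
                                  grid_scores, population_autocorrelogram)


@pytest.fixture(scope="module")
def ideal_map():
    return grid_kernel(pixel_coordinates(), 60.0)


class TestAutocorrelogram:
    def test_ideal_map_has_six_sixty_degree_maxima(self, ideal_map):
        ac = compute_autocorrelogram(ideal_map)
        spacing, flagged = estimate_spacing(ac)
        assert not flagged
        mx = detect_maxima(ac, spacing)
        assert len(mx) == 6
        ang = np.sort(np.rad2deg(np.arctan2(mx[:, 1], mx[:, 0])) % 360)
        gaps = np.diff(np.r_[ang, ang[0] + 360])
        np.testing.assert_allclose(gaps, 60.0, atol=7.0)
        np.testing.assert_allclose(np.hypot(*mx.T), spacing, rtol=0.1)

    def test_affine_map_transform_leaves_correlation_unchanged(self,
                                                               ideal_map):
        a = compute_autocorrelogram(ideal_map)
        b = compute_autocorrelogram(3.0 * ideal_map + 2.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_zero_lag_is_the_raw_maximum(self, ideal_map):
        ac = compute_autocorrelogram(ideal_map)
        c = ac.center
        assert ac.raw[c, c] == pytest.approx(ac.raw.max())
        np.testing.assert_allclose(ac.raw, ac.raw[::-1, ::-1], atol=1e-9)

    def test_constant_map_is_flagged(self):
        s = grid_scores(np.full((41, 41), 2.0))
        assert s.flagged


class TestSpacing:
    def test_design_spacing_recovered_within_one_bin(self, ideal_map):
        spacing, flagged = estimate_spacing(compute_autocorrelogram(ideal_map))
        assert not flagged
        assert abs(spacing - 60.0) <= 2.4

    @pytest.mark.parametrize("target", [30.0, 36.0, 60.0])
    def test_design_spacings_recovered(self, target):
        m = grid_kernel(pixel_coordinates(), target)
        spacing, flagged = estimate_spacing(compute_autocorrelogram(m))
        assert not flagged
        assert abs(spacing - target) <= 2.4

    @pytest.mark.parametrize("base", [22.5, 30.0])
    def test_covariance_under_spatial_rescaling(self, base):
        def sp(s):
            m = grid_kernel(pixel_coordinates(), s)
            spacing, flagged = estimate_spacing(compute_autocorrelogram(m))
            assert not flagged
            return spacing
        # doubling the map scale doubles the estimate, within one bin at
        # each of the two scales
        assert abs(sp(2 * base) - 2 * sp(base)) <= 3 * 2.4

    def test_noise_maps_are_flagged(self):
        rng = np.random.default_rng(0)
        flags = [grid_scores(rng.uniform(0, 1, (41, 41))).flagged
                 for _ in range(30)]
        assert np.mean(flags) >= 0.95


class TestGridness:
    def test_ideal_map_exceeds_one(self, ideal_map):
        s = grid_scores(ideal_map)
        assert s.gridness > 1.0

    def test_white_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        g = [compute_gridness(compute_autocorrelogram(
            rng.uniform(0, 1, (41, 41)))) for _ in range(30)]
        assert np.max(np.abs(g)) < 0.2

    def test_square_lattice_scores_low(self):
        xy = pixel_coordinates()
        k = 2 * np.pi / 45.0
        sq = np.cos(k * xy[..., 0]) + np.cos(k * xy[..., 1])
        ac = compute_autocorrelogram(sq)
        assert compute_gridness(ac, 45.0) < 0.2

    def test_invariant_under_sixty_degree_rotation(self, ideal_map):
        rot = grid_kernel(pixel_coordinates(), 60.0,
                          orientation=np.deg2rad(60.0))
        g0 = grid_scores(ideal_map).gridness
        g1 = grid_scores(rot).gridness
        assert g1 == pytest.approx(g0, rel=0.05)


class TestAngularSpread:
    def test_identical_maps_have_zero_spread(self, ideal_map):
        maps = np.stack([ideal_map] * 5)
        assert compute_angular_spread(maps) == pytest.approx(0.0, abs=1e-9)

    def test_spread_grows_with_orientation_jitter(self):
        def jittered(sd_deg, seed):
            rng = np.random.default_rng(seed)
            return np.stack([
                grid_kernel(pixel_coordinates(), 60.0,
                            orientation=np.deg2rad(rng.normal(0, sd_deg)))
                for _ in range(8)])
        s_small = compute_angular_spread(jittered(2.0, 0))
        s_big = compute_angular_spread(jittered(8.0, 1))
        assert s_small < s_big

    def test_two_subpopulations_offset_thirty_degrees_spread_widely(self):
        maps = np.concatenate([
            np.stack([grid_kernel(pixel_coordinates(), 60.0)] * 4),
            np.stack([grid_kernel(pixel_coordinates(), 60.0,
                                  orientation=np.deg2rad(30.0))] * 4)])
        assert compute_angular_spread(maps) > 8.0

    def test_needs_two_usable_maps(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            compute_angular_spread(rng.uniform(0, 1, (3, 41, 41)))


class TestPopulationAutocorrelogram:
    def test_identical_cells_equal_individual(self, ideal_map):
        maps = np.stack([ideal_map] * 3)
        pac = population_autocorrelogram(maps)
        ac = compute_autocorrelogram(ideal_map)
        np.testing.assert_allclose(pac.values, ac.values, atol=1e-12)

    def test_aligned_population_is_hexagonal_and_tight(self):
        maps = ideal_grid_population(16, 60.0, "random", noise_sd=0.02,
                                     seed=4)
        pac = population_autocorrelogram(maps)
        spacing, flagged = estimate_spacing(pac)
        assert not flagged
        pop_g = compute_gridness(pac, spacing)
        indiv = np.mean([grid_scores(m).gridness for m in maps])
        assert pop_g == pytest.approx(indiv, rel=0.1)
        assert compute_angular_spread(maps) < 5.0

    def test_random_orientations_destroy_the_mean_modulation(self):
        rng = np.random.default_rng(5)
        maps = np.stack([
            grid_kernel(pixel_coordinates(), 60.0,
                        orientation=rng.uniform(0, np.pi / 3))
            for _ in range(12)])
        pac = population_autocorrelogram(maps)
        spacing, _ = estimate_spacing(pac)
        aligned = population_autocorrelogram(
            np.stack([grid_kernel(pixel_coordinates(), 60.0)] * 12))
        sp_a, _ = estimate_spacing(aligned)
        assert compute_gridness(pac, spacing) < \
            0.5 * compute_gridness(aligned, sp_a)
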