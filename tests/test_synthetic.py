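"""Generator tests: sampling, packing, rasterization, image formation."""

import math

import numpy as np
import pytest

from amyloidscope import (ADULT_SIZE_DISTRIBUTION, CohortConfig,
                          ConfigurationError, GroundTruth, GroupConfig,
                          NoiseConfig, PackingError, SimulationConfig,
                          SizeDistributionSpec, add_noise_and_quantize,
                          add_stripes, add_vessels, apply_attenuation,
                          apply_lightsheet_blur, generate_cohort,
                          place_plaques, rasterize, sample_diameters)
from amyloidscope.synthetic import fwhm_to_sigma, lightsheet_sigma_z_um


# -------------------------------------------------------------- sampling

class TestSampleDiameters:
    def test_adult_bin_fractions_match_spec(self):
        d = sample_diameters(ADULT_SIZE_DISTRIBUTION, 10_000, seed=7)
        edges = np.asarray(ADULT_SIZE_DISTRIBUTION.bin_edges_um)
        probs = np.asarray(ADULT_SIZE_DISTRIBUTION.probabilities)
        frac = np.histogram(d, bins=edges)[0] / d.size
        assert np.all(np.abs(frac - probs) <= 0.015)

    def test_empty_and_support(self):
        assert sample_diameters(ADULT_SIZE_DISTRIBUTION, 0, seed=0).size == 0
        one_bin = SizeDistributionSpec.empirical([10.0, 20.0], [1.0])
        d = sample_diameters(one_bin, 1000, seed=0)
        assert np.all((d >= 10.0) & (d < 20.0))

    def test_reproducible_and_invalid_probabilities(self):
        a = sample_diameters(ADULT_SIZE_DISTRIBUTION, 50, seed=3)
        b = sample_diameters(ADULT_SIZE_DISTRIBUTION, 50, seed=3)
        assert np.array_equal(a, b)
        with pytest.raises(ConfigurationError):
            SizeDistributionSpec(mode="empirical_bins",
                                 bin_edges_um=(8.0, 10.0, 20.0),
                                 probabilities=(0.9, 0.3))

    def test_truncated_lognormal_support_and_moment(self):
        spec = SizeDistributionSpec.truncated_lognormal(3.0, 0.5, 10.0, 40.0)
        d = sample_diameters(spec, 4000, seed=5)
        assert np.all((d >= 10.0) & (d <= 40.0))
        assert abs(spec.moment(1) - d.mean()) < 0.5

    def test_empirical_moment_matches_monte_carlo(self):
        d = sample_diameters(ADULT_SIZE_DISTRIBUTION, 200_000, seed=11)
        assert abs(ADULT_SIZE_DISTRIBUTION.moment(3) - np.mean(d ** 3)) \
            < 0.02 * ADULT_SIZE_DISTRIBUTION.moment(3)


# -------------------------------------------------------------- placement

class TestPlacePlaques:
    def test_empty(self):
        mask = np.ones((5, 5, 5), bool)
        assert place_plaques(mask, [], 4.0, seed=0).shape == (0, 3)

    def test_nonoverlap_brute_force_oracle(self):
        # 50 spheres of d=20 um in a 1 mm^3 mask, min separation 4 um
        mask = np.ones((50, 50, 50), bool)  # 20 um voxels -> 1 mm^3
        d = np.full(50, 20.0)
        centers = place_plaques(mask, d, 4.0, seed=2,
                                voxel_size_um=(20.0, 20.0, 20.0))
        for i in range(50):
            for j in range(i + 1, 50):
                dist = math.dist(centers[i], centers[j])
                assert dist > 20.0 + 4.0

    def test_infeasible_raises_packing_error(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        with pytest.raises(PackingError) as err:
            place_plaques(mask, [6.0, 6.0], 2.0, seed=0,
                          voxel_size_um=(2.0, 2.0, 2.0),
                          max_total_tries=500)
        assert err.value.achieved < 2


# -------------------------------------------------------------- rasterize

def _enumerate_sphere_voxels(center, diameter, shape, voxel):
    """Independent voxel-centre membership oracle (triple loop)."""
    r2 = (diameter / 2.0) ** 2
    count = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = ((i + 0.5) * voxel[0], (j + 0.5) * voxel[1],
                     (k + 0.5) * voxel[2])
                if sum((a - b) ** 2 for a, b in zip(p, center)) <= r2:
                    count += 1
    return count


class TestRasterize:
    def test_sphere_voxel_count(self, quiet_config, rng):
        ideal = (4.0 / 3.0) * math.pi * 5.0 ** 3 / 8.0  # ~65.4 voxels
        for _ in range(5):
            c = rng.uniform(20.0, 60.0, 3)
            grid = rasterize([c], [10.0], quiet_config)
            count = int((grid > quiet_config.background_level).sum())
            oracle = _enumerate_sphere_voxels(
                c, 10.0, quiet_config.grid_shape, quiet_config.voxel_size_um)
            assert count == oracle
            assert abs(count - ideal) <= 0.15 * ideal

    def test_empty_is_uniform_background(self, quiet_config):
        grid = rasterize(np.empty((0, 3)), [], quiet_config)
        assert np.all(grid == quiet_config.background_level)

    def test_centroid_matches_planted_center(self, quiet_config, rng):
        c = rng.uniform(25.0, 55.0, 3)
        grid = rasterize([c], [14.0], quiet_config)
        zz, yy, xx = np.nonzero(grid > quiet_config.background_level)
        v = np.asarray(quiet_config.voxel_size_um)
        centroid = np.array([(zz + 0.5).mean(), (yy + 0.5).mean(),
                             (xx + 0.5).mean()]) * v
        assert np.all(np.abs(centroid - c) <= v / 2)

    def test_supersample_partial_volume(self, quiet_config):
        grid = rasterize([[40.0, 40.0, 40.0]], [10.0], quiet_config,
                         supersample=2)
        inten = grid - quiet_config.background_level
        frac = inten.sum() / quiet_config.plaque_amplitude
        true_voxels = (4.0 / 3.0) * math.pi * 125.0 / 8.0
        assert abs(frac - true_voxels) < 0.1 * true_voxels

    def test_center_outside_grid_rejected(self, quiet_config):
        with pytest.raises(ConfigurationError):
            rasterize([[500.0, 10.0, 10.0]], [8.0], quiet_config)


# -------------------------------------------------------------- artifacts

class TestArtifacts:
    def test_no_vessels_is_identity(self, quiet_config):
        grid = np.full(quiet_config.grid_shape, 100.0, np.float32)
        truth = GroundTruth(plaques=GroundTruth.empty_plaque_frame())
        out = add_vessels(grid.copy(), truth, 0, seed=0, config=quiet_config)
        assert np.array_equal(out, grid)

    def test_vessel_elongation_pca_oracle(self):
        cfg = SimulationConfig(grid_shape=(30, 30, 220),
                               voxel_size_um=(2.0, 2.0, 2.0))
        grid = np.full(cfg.grid_shape, cfg.background_level, np.float32)
        truth = GroundTruth(plaques=GroundTruth.empty_plaque_frame())
        # a straight tube: one segment, radius 5, length ~400 um
        add_vessels(grid, truth, 1, radius_um_range=(5.0, 5.0), seed=4,
                    config=cfg, segment_length_um_range=(400.0, 400.0))
        coords = np.argwhere(grid > cfg.background_level).astype(float)
        coords -= coords.mean(axis=0)
        eig = np.linalg.eigvalsh(coords.T @ coords / len(coords))
        assert math.sqrt(eig[-1] / max(eig[0], 1e-9)) > 10

    def test_vessel_voxels_recorded_in_truth(self, quiet_config):
        grid = np.full(quiet_config.grid_shape,
                       quiet_config.background_level, np.float32)
        truth = GroundTruth(plaques=GroundTruth.empty_plaque_frame())
        add_vessels(grid, truth, 2, radius_um_range=(3.0, 5.0), seed=9,
                    config=quiet_config, segment_length_um_range=(20.0, 40.0))
        lit = {tuple(v) for v in
               np.argwhere(grid > quiet_config.background_level)}
        recorded = {tuple(v) for ves in truth.vessels for v in ves.voxels}
        assert lit <= recorded

    def test_stripes_shape_and_truth(self, quiet_config):
        grid = np.full(quiet_config.grid_shape,
                       quiet_config.background_level, np.float32)
        truth = GroundTruth(plaques=GroundTruth.empty_plaque_frame())
        out = add_stripes(grid.copy(), truth, 0, seed=0, config=quiet_config)
        assert np.array_equal(out, grid)
        add_stripes(grid, truth, 1, seed=3, config=quiet_config)
        zz, yy, xx = np.nonzero(grid > quiet_config.background_level)
        x_ext = xx.max() - xx.min() + 1
        y_ext = yy.max() - yy.min() + 1
        z_ext = zz.max() - zz.min() + 1
        assert x_ext >= 10 * max(y_ext, z_ext)
        recorded = {tuple(v) for s in truth.stripes for v in s.voxels}
        lit = set(zip(zz.tolist(), yy.tolist(), xx.tolist()))
        assert lit <= recorded


# ---------------------------------------------------------- image formation

class TestLightsheetBlur:
    def test_zero_sigma_is_identity(self, rng):
        cfg = SimulationConfig(grid_shape=(16, 16, 16), lateral_fwhm_um=0.0,
                               axial_fwhm_um=0.0)
        grid = rng.uniform(0, 4000, cfg.grid_shape).astype(np.float32)
        assert np.allclose(apply_lightsheet_blur(grid, cfg), grid)

    def test_sigma_profile_closed_form(self):
        cfg = SimulationConfig(grid_shape=(16, 16, 256),
                               field_center_x_um=200.0)
        sig0 = fwhm_to_sigma(cfg.axial_fwhm_um)
        xr = cfg.rayleigh_range_um
        at_waist = lightsheet_sigma_z_um(np.array([200.0]), cfg)[0]
        at_xr = lightsheet_sigma_z_um(np.array([200.0 + xr]), cfg)[0]
        assert at_waist == pytest.approx(sig0)
        assert at_xr == pytest.approx(sig0 * math.sqrt(2.0))

    def test_invalid_optics_rejected(self):
        cfg = SimulationConfig(grid_shape=(8, 8, 8),
                               sheet_waist_halfwidth_w0_um=0.0)
        with pytest.raises(ConfigurationError):
            apply_lightsheet_blur(np.zeros((8, 8, 8), np.float32), cfg)


class TestAttenuation:
    def test_zero_mu_identity(self, rng):
        grid = rng.uniform(0, 100, (8, 8, 8)).astype(np.float32)
        assert np.array_equal(apply_attenuation(grid, 0.0), grid)

    def test_depth_ratio_closed_form(self):
        cfg = SimulationConfig(grid_shape=(20, 200, 20),
                               voxel_size_um=(10.0, 10.0, 10.0),
                               background_level=0.0)
        centers = [[95.0, 495.0, 95.0], [95.0, 1495.0, 95.0]]
        grid = rasterize(centers, [40.0, 40.0], cfg)
        out = apply_attenuation(grid, 1.0, cfg.voxel_size_um, depth_axis=1)
        peak_shallow = out[:, 40:60, :].max()
        peak_deep = out[:, 140:160, :].max()
        assert peak_shallow / peak_deep == pytest.approx(math.e, rel=0.05)

    def test_monotone_mean_slice_intensity(self):
        grid = np.full((4, 64, 4), 1000.0, np.float32)
        out = apply_attenuation(grid, 0.8, (10.0, 10.0, 10.0), depth_axis=1)
        means = out.mean(axis=(0, 2))
        assert np.all(np.diff(means) <= 0)


class TestNoiseAndQuantize:
    def test_zero_noise_is_pure_rounding(self):
        cfg = SimulationConfig(grid_shape=(4, 4, 4),
                               noise=NoiseConfig(gaussian_sigma=0.0))
        grid = np.full(cfg.grid_shape, 1234.4, np.float32)
        out = add_noise_and_quantize(grid, cfg, seed=0)
        assert out.dtype == np.uint16 and np.all(out == 1234)

    def test_range_and_reproducibility(self):
        cfg = SimulationConfig(grid_shape=(8, 8, 8),
                               noise=NoiseConfig(gaussian_sigma=500.0,
                                                 poisson=True))
        grid = np.full(cfg.grid_shape, 3800.0, np.float32)
        a = add_noise_and_quantize(grid, cfg, seed=42)
        b = add_noise_and_quantize(grid, cfg, seed=42)
        assert a.min() >= 0 and a.max() <= 4095
        assert np.array_equal(a, b)


# ------------------------------------------------------------------ cohort

class TestGenerateCohort:
    def test_two_tiny_groups(self):
        dist = SizeDistributionSpec.empirical([10.0, 20.0], [1.0])
        sim = SimulationConfig(voxel_size_um=(4.0, 4.0, 4.0),
                               sheet_waist_halfwidth_w0_um=200.0)
        cohort = CohortConfig(
            groups=(GroupConfig(name="young", n_animals=1,
                                size_distribution=dist, exact_total=20),
                    GroupConfig(name="adult", n_animals=1,
                                size_distribution=dist, exact_total=20)),
            sim=sim)
        scenes = generate_cohort(cohort, seed=5)
        assert [s.animal_id for s in scenes] == ["young_01", "adult_01"]
        assert len(scenes[0].truth.plaques) == 20
        assert len(scenes[1].truth.plaques) == 20
        # distinct seeds per group -> distinct volumes
        assert scenes[0].volume.shape == scenes[1].volume.shape
        assert not np.array_equal(scenes[0].volume, scenes[1].volume)

    def test_exact_totals_count_oracle(self):
        dist = SizeDistributionSpec.empirical([10.0, 30.0], [1.0])
        sim = SimulationConfig(voxel_size_um=(4.0, 4.0, 4.0),
                               sheet_waist_halfwidth_w0_um=200.0)
        cohort = CohortConfig(
            groups=(GroupConfig(name="g", n_animals=2,
                                size_distribution=dist, exact_total=100),),
            sim=sim)
        scenes = generate_cohort(cohort, seed=8)
        in_cubes = 0
        for s in scenes:
            pts = s.truth.plaques[["z_um", "y_um", "x_um"]].to_numpy()
            for cube in s.cubes:
                o = np.asarray(cube.origin_um)
                inside = np.all((pts >= o) & (pts < o + cube.edge_um), axis=1)
                in_cubes += int(inside.sum())
        assert in_cubes == 100

    def test_reproducible_bit_identical(self):
        dist = SizeDistributionSpec.empirical([10.0, 20.0], [1.0])
        sim = SimulationConfig(voxel_size_um=(4.0, 4.0, 4.0),
                               sheet_waist_halfwidth_w0_um=200.0)
        cohort = CohortConfig(
            groups=(GroupConfig(name="g", n_animals=1,
                                size_distribution=dist, exact_total=25),),
            sim=sim)
        a = generate_cohort(cohort, seed=3)[0]
        b = generate_cohort(cohort, seed=3)[0]
        assert np.array_equal(a.volume, b.volume)
        assert a.truth.plaques.equals(b.truth.plaques)

    def test_nonoverlap_invariant_brute_force(self):
        scenes = generate_cohort(CohortConfig(
            groups=(GroupConfig(name="g", n_animals=1,
                                size_distribution=ADULT_SIZE_DISTRIBUTION,
                                exact_total=120),),
            sim=SimulationConfig(voxel_size_um=(2.0, 2.0, 2.0),
                                 sheet_waist_halfwidth_w0_um=200.0)), seed=2)
        df = scenes[0].truth.plaques
        pts = df[["z_um", "y_um", "x_um"]].to_numpy()
        radii = df["diameter_um"].to_numpy() / 2.0
        for i in range(len(df)):
            for j in range(i + 1, len(df)):
                assert math.dist(pts[i], pts[j]) > radii[i] + radii[j]

    def test_density_mode_places_in_cortex(self):
        cohort = CohortConfig(
            groups=(GroupConfig(name="g", n_animals=1,
                                size_distribution=ADULT_SIZE_DISTRIBUTION,
                                density_per_mm3=3000.0),),
            sim=SimulationConfig(grid_shape=(48, 72, 72),
                                 sheet_waist_halfwidth_w0_um=200.0))
        scene = generate_cohort(cohort, seed=6)[0]
        assert scene.cubes is None
        pts = scene.truth.plaques[["z_um", "y_um", "x_um"]].to_numpy()
        idx = np.floor(pts / 2.0).astype(int)
        assert np.all(scene.cortex_mask[idx[:, 0], idx[:, 1], idx[:, 2]])
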