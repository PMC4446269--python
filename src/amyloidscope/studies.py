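"""Canonical in-silico study conditions for validating the pipeline.

These functions freeze the simulated experiments the package uses to check
itself end to end: planted-total recovery cohorts, the empirical adult
size-distribution cohort, the diameter sweep for the counting floor, and
the off-waist merging experiment.  They exist in the library (rather than
in test code) so the same conditions can be rerun from scripts.

Problem sizes: recovery cohorts use 4 um voxels and uniform 10-40 um
plaques; the size-distribution cohort uses 2 um voxels so the narrow
8-10 um bin is resolved.  Both image with mild Gaussian read noise and a
wide-waist sheet (negligible Rayleigh divergence across the field), i.e.
a constant, modest PSF — the regime in which counting is expected to be
exact.  The off-waist study instead uses the default narrow waist to
exhibit the merging artifact.
"""

from __future__ import annotations

import math
from typing import Dict, Sequence

import numpy as np

from .quantify import cube_count_density, size_histogram, SizeHistogram
from .segmentation import SegmentationParams, label_components, segment_volume
from .synthetic import (ADULT_SIZE_DISTRIBUTION, CohortConfig, GroupConfig,
                        NoiseConfig, SimulationConfig, SizeDistributionSpec,
                        apply_lightsheet_blur, generate_cohort, rasterize)

__all__ = [
    "recovery_cohort_config",
    "recovery_segmentation_params",
    "run_planted_recovery",
    "run_size_distribution_study",
    "run_diameter_sweep",
    "run_offwaist_merging_study",
]

#: Fixed threshold for recovery studies: well above background + noise
#: (background 100, sigma 20), well below plaque amplitude 3000, so mild
#: blur cannot push small plaques below it.
RECOVERY_THRESHOLD = 1000.0

#: Mid-amplitude threshold used with partial-volume (supersampled)
#: rasterization: foreground voxels are those at least ~half plaque-filled,
#: which tracks the true sphere surface and keeps measured volumes unbiased.
MIDPOINT_THRESHOLD = 1600.0


def _wide_waist_sim(voxel_um: float) -> SimulationConfig:
    return SimulationConfig(
        voxel_size_um=(voxel_um,) * 3,
        sheet_waist_halfwidth_w0_um=200.0,   # Rayleigh range >> field of view
        noise=NoiseConfig(gaussian_sigma=20.0))


def recovery_cohort_config(totals: Dict[str, int], n_animals: int = 5,
                           voxel_um: float = 4.0) -> CohortConfig:
    """Exact-totals cohort: uniform 10-40 um plaques planted in six cubes
    per animal with > 2 voxel separations, mild noise, modest constant
    blur and no vessel/stripe artifacts."""
    dist = SizeDistributionSpec.empirical([10.0, 40.0], [1.0])
    groups = tuple(
        GroupConfig(name=name, n_animals=n_animals, size_distribution=dist,
                    exact_total=int(total))
        for name, total in totals.items())
    return CohortConfig(groups=groups, sim=_wide_waist_sim(voxel_um),
                        min_separation_um=12.0)


def recovery_segmentation_params() -> SegmentationParams:
    return SegmentationParams(fixed_threshold=RECOVERY_THRESHOLD)


def run_planted_recovery(totals: Dict[str, int], seed: int,
                         n_animals: int = 5, voxel_um: float = 4.0
                         ) -> Dict[str, int]:
    """Generate, image, segment and count each group's cohort; returns the
    pipeline count summed over all sample cubes, per group."""
    cohort = recovery_cohort_config(totals, n_animals, voxel_um)
    params = recovery_segmentation_params()
    counted = {name: 0 for name in totals}
    for scene in generate_cohort(cohort, seed):
        _, records = segment_volume(scene.volume, params,
                                    scene.config.voxel_size_um)
        retained = records[records["retained"]]
        counted[scene.group] += sum(
            cube_count_density(retained, cube)[0] for cube in scene.cubes)
    return counted


def run_size_distribution_study(seed: int, n_total: int = 9999,
                                n_animals: int = 3,
                                dist: SizeDistributionSpec = ADULT_SIZE_DISTRIBUTION
                                ) -> SizeHistogram:
    """Adult-type cohort drawn from the empirical size table, rasterized at
    2 um voxels without blur, segmented at the mid-amplitude threshold;
    returns the size histogram of recovered equivalent diameters."""
    cohort = CohortConfig(
        groups=(GroupConfig(name="adult", n_animals=n_animals,
                            size_distribution=dist, exact_total=int(n_total)),),
        sim=_wide_waist_sim(2.0), min_separation_um=6.0, apply_blur=False)
    params = SegmentationParams(fixed_threshold=MIDPOINT_THRESHOLD)
    diameters = []
    for scene in generate_cohort(cohort, seed):
        _, records = segment_volume(scene.volume, params,
                                    scene.config.voxel_size_um)
        retained = records[records["retained"]]
        diameters.append(retained["equivalent_diameter_um"].to_numpy())
    return size_histogram(np.concatenate(diameters),
                          edges_um=dist.bin_edges_um)


def run_diameter_sweep(diameters_um: Sequence[float] = tuple(range(4, 61)),
                       spacing_um: float = 12.0):
    """Noise- and blur-free sweep scene: one sphere per requested diameter
    in a row along x; segment at defaults and return the retained records.

    Used to verify the counting floor: no retained object may fall below
    the 8 um minimum equivalent diameter.
    """
    diams = np.asarray(sorted(diameters_um), float)
    d_max = diams.max()
    margin = d_max / 2.0 + 6.0
    xs = []
    x = margin
    prev_r = 0.0
    for d in diams:
        x += prev_r + d / 2.0 + spacing_um
        xs.append(x)
        prev_r = d / 2.0
    extent_yz = d_max + 2 * margin
    cfg = SimulationConfig(
        grid_shape=(int(math.ceil(extent_yz / 2.0)),
                    int(math.ceil(extent_yz / 2.0)),
                    int(math.ceil((x + margin) / 2.0))),
        voxel_size_um=(2.0, 2.0, 2.0), lateral_fwhm_um=0.0, axial_fwhm_um=0.0,
        noise=NoiseConfig(gaussian_sigma=0.0))
    c = extent_yz / 2.0
    centers = [[c, c, xi] for xi in xs]
    grid = rasterize(centers, diams, cfg)
    params = SegmentationParams(fixed_threshold=MIDPOINT_THRESHOLD)
    _, records = segment_volume(grid, params, cfg.voxel_size_um)
    return records[records["retained"]]


def run_offwaist_merging_study(pair_diameter_um: float = 40.0,
                               gap_um: float = 6.0, n_pairs: int = 4):
    """Image the same scene at the sheet waist and at three Rayleigh ranges
    off-waist; return the fraction of segmented objects with equivalent
    diameter above 50 um in each case.

    The scene holds pairs of equal spheres separated by ``gap_um`` along z
    (plus two isolated smaller spheres).  At the waist the axial PSF
    resolves the gap; off-waist the thickened sheet merges each pair into
    one object whose equivalent diameter exceeds 50 um.
    """
    d = pair_diameter_um
    cfg = SimulationConfig(
        grid_shape=(100, 40 + n_pairs * 30, 30),
        voxel_size_um=(2.0, 2.0, 2.0),
        noise=NoiseConfig(gaussian_sigma=0.0))
    z0 = 100.0 - (d + gap_um) / 2.0
    z1 = 100.0 + (d + gap_um) / 2.0
    centers, diams = [], []
    for i in range(n_pairs):
        y = 40.0 + i * 60.0
        centers += [[z0, y, 30.0], [z1, y, 30.0]]
        diams += [d, d]
    centers += [[40.0, 25.0, 30.0], [160.0, 25.0, 30.0]]
    diams += [20.0, 20.0]

    x_scene = cfg.extent_um[2] / 2.0
    fractions = {}
    for tag, offset in (("waist", 0.0), ("off_waist", 3.0)):
        from dataclasses import replace
        c = replace(cfg, field_center_x_um=x_scene
                    - offset * cfg.rayleigh_range_um)
        scene = rasterize(centers, diams, c, supersample=2)
        blurred = apply_lightsheet_blur(scene, c)
        mask = blurred >= MIDPOINT_THRESHOLD
        _, records = label_components(mask, 26, c.voxel_size_um)
        fractions[tag] = float(
            (records["equivalent_diameter_um"] > 50.0).mean())
    return fractions["waist"], fractions["off_waist"]
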