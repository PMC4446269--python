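import numpy as np
import pytest

from amyloidscope import NoiseConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Small noise-free, blur-free configuration for exact oracles."""
    return SimulationConfig(
        grid_shape=(40, 40, 40), voxel_size_um=(2.0, 2.0, 2.0),
        lateral_fwhm_um=0.0, axial_fwhm_um=0.0,
        noise=NoiseConfig(gaussian_sigma=0.0, poisson=False))


def make_recovery_cohort(totals, n_animals=2, voxel=4.0, seed=1):
    """Exact-totals cohort with mild noise, wide-waist (constant) blur and
    10-40 um plaques, mirroring the planted-recovery study conditions."""
    from amyloidscope import (CohortConfig, GroupConfig, NoiseConfig,
                              SimulationConfig, SizeDistributionSpec,
                              generate_cohort)
    dist = SizeDistributionSpec.empirical([10.0, 40.0], [1.0])
    sim = SimulationConfig(voxel_size_um=(voxel,) * 3,
                           sheet_waist_halfwidth_w0_um=200.0,
                           noise=NoiseConfig(gaussian_sigma=20.0))
    groups = tuple(
        GroupConfig(name=name, n_animals=n_animals, size_distribution=dist,
                    exact_total=total)
        for name, total in totals.items())
    cohort = CohortConfig(groups=groups, sim=sim, min_separation_um=12.0)
    return generate_cohort(cohort, seed)
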