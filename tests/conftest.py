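import numpy as np
import pytest

from dcx.config import RunConfig
from dcx.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted-effect cohort shared across tests (read-only)."""
    cfg = SimConfig(
        n_per_group=6, n_rois=20, n_modules=4, n_volumes=80, n_drop=5,
        planted_effects={3: ("FuG_L_3_3", 0.4), 11: ("PhG_R_6_4", -0.4)},
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_voxel_cohort():
    cfg = SimConfig(
        n_per_group=6, n_rois=10, n_modules=2, n_volumes=60, n_drop=5,
        voxel_grid=(6, 6, 3), voxels_per_roi=5, voxel_noise_sd=0.4,
        planted_effects={2: ("FuG_L_3_3", 0.45), 7: ("PhG_R_6_4", -0.45)},
        seed=21,
    )
    return simulate_cohort(cfg, mode="voxel")


@pytest.fixture
def default_run():
    return RunConfig()
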