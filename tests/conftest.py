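import numpy as np
import pytest

from bedomics.grids import ROIMask, VolumeGrid
from bedomics.preprocess import DiscretizedVolume
from bedomics.synthetic import SyntheticCohortConfig, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> SyntheticCohortConfig:
    """Small, fast phantom geometry shared across tests."""
    return SyntheticCohortConfig(
        n_patients=10, grid_shape=(20, 40, 40), voxel_spacing=(3.0, 3.0, 3.0), seed=11
    )


@pytest.fixture(scope="session")
def phantom(small_config):
    return generate_phantom(small_config, 0)


def random_discretized(rng: np.random.Generator, shape=(5, 5, 5), n_bins=6,
                       mask_fraction=1.0) -> DiscretizedVolume:
    """A random small discretized grid (optionally with holes in the ROI)."""
    mask = rng.uniform(size=shape) < mask_fraction
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_bins + 1, size=int(mask.sum()))
    return DiscretizedVolume(levels=levels, mask=mask, n_bins=n_bins,
                             intensity_range=(0.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_grid(values, spacing=(1.0, 1.0, 1.0)) -> VolumeGrid:
    return VolumeGrid(np.asarray(values, dtype=float), spacing)


def full_mask(grid: VolumeGrid, name="roi") -> ROIMask:
    return ROIMask(np.ones(grid.shape, dtype=bool), grid.spacing, grid.origin, roi_name=name)
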