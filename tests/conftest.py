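import numpy as np
import pytest

from phantomtract import (
    TrackingConfig,
    build_phantom,
    demo_spec,
    junction_spec,
    straight_tube_spec,
)
from phantomtract.grid import VoxelGrid
from phantomtract.phantom import MAX_POPULATIONS, FiberField


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight tube along +x, zero dispersion, with seed/waypoint/exclusions."""
    return build_phantom(straight_tube_spec(), TrackingConfig.human(n_samples=100,
                                                                    rng_seed=11))


@pytest.fixture(scope="session")
def junction_phantom():
    """L-shaped bundle with an abrupt 90-degree orientation flip."""
    return build_phantom(junction_spec(), TrackingConfig.human(n_samples=50,
                                                               rng_seed=12))


@pytest.fixture(scope="session")
def demo():
    """The two-source merged-bundle phantom spec."""
    return demo_spec(rng_seed=13)


def make_field(grid_shape, populations, voxel_size=1.0, n_samples=4):
    """Hand-built fiber field: ``populations`` maps voxel (i,j,k) to a list of
    (mean, fraction) pairs; dispersion is zero so samples equal the means."""
    grid = VoxelGrid.isotropic(grid_shape, voxel_size)
    index = np.full((*grid_shape, MAX_POPULATIONS), -1, dtype=np.int32)
    means, fracs = [], []
    for ijk, pops in populations.items():
        for slot, (mean, frac) in enumerate(pops):
            index[(*ijk, slot)] = len(means)
            m = np.asarray(mean, dtype=float)
            means.append(m / np.linalg.norm(m))
            fracs.append(frac)
    means = np.asarray(means).reshape(-1, 3)
    fracs = np.asarray(fracs, dtype=float)
    samples = np.repeat(means[:, None, :], n_samples, axis=1)
    return FiberField(grid, index, means, fracs, np.zeros(len(fracs)), samples)


@pytest.fixture
def one_voxel_field():
    return make_field((1, 1, 1), {(0, 0, 0): [((1.0, 0.0, 0.0), 0.8)]})
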