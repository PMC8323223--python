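import numpy as np
import pytest

from neurorender.fixtures import FixtureSpec, synth_icosphere, synth_tractography, synth_volume_two_class


@pytest.fixture
def small_tract():
    """10 fibers in 2 bundles of 5 (contiguous index ranges)."""
    return synth_tractography(FixtureSpec(seed=7, n_fibers=10, n_bundles=2, points_per_fiber=8))


@pytest.fixture
def two_class_volume():
    return synth_volume_two_class(FixtureSpec(seed=3, volume_dims=(16, 16, 16)))


@pytest.fixture
def icosphere():
    return synth_icosphere(1)


@pytest.fixture
def ramp_volume():
    """data[i,j,k] = 100*i + 10*j + k on a 3x3x3 grid, unit voxels."""
    from neurorender.io_formats import Volume

    i, j, k = np.meshgrid(np.arange(3), np.arange(3), np.arange(3), indexing="ij")
    return Volume(data=(100 * i + 10 * j + k).astype(np.float32))
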