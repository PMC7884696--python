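import numpy as np
import pytest

from lesiontopo.phantom import PhantomConfig, generate_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default phantom atlas, shared across tests (construction is pure)."""
    return generate_atlas(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_atlas():
    """Small atlas for brute-force voxel-loop oracles."""
    return generate_atlas(
        PhantomConfig(grid_shape=(32, 32, 16), voxel_size_mm=(2.0, 2.0, 3.0),
                      n_structures_per_hemisphere=4, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
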