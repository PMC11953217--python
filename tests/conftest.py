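import numpy as np
import pytest

from fodgan.phantoms import PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: 16x16x8 grid, 2 mm voxels, two crossing bundles."""
    return PhantomSpec(grid_dims=(16, 16, 8), voxel_size=(2.0, 2.0, 2.0),
                       lmax=6, seed=3)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def tiny_train_cohort():
    """Eight 32x32x16 lmax=6 phantoms for fast training-mechanics tests."""
    spec = PhantomSpec(grid_dims=(32, 32, 16), voxel_size=(2.0, 2.0, 2.0),
                       lmax=6, seed=0)
    return make_cohort(8, spec, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
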