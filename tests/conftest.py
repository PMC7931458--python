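import numpy as np
import pytest

from munet import petsim, phantom


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom set shared across tests (deterministic)."""
    return phantom.make_phantom(shape=(32, 32, 32), voxel_size=(2.0, 2.0, 2.0),
                                n_lesions=1, seed=11)


@pytest.fixture(scope="session")
def small_geometry():
    """Small slice-wise geometry matching the 32^3 phantom."""
    return petsim.default_geometry((32, 32, 32), (2.0, 2.0, 2.0), n_angles=24)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
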