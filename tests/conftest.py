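import numpy as np
import pytest

from pmqsm import (AcquisitionParams, PhantomSpec, build_phantom,
                   simulate_acquisition)


@pytest.fixture(scope="session")
def params_2mm():
    return AcquisitionParams(voxel_size_mm=(2.0, 2.0, 2.0), n_repeats=1)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(32, 32, 32))


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec, voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def clean_data(small_truth, small_spec, params_2mm):
    """Noiseless, drift-free, single-coil acquisition of the small phantom."""
    return simulate_acquisition(small_truth, small_spec, params_2mm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
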