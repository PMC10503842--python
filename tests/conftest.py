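import numpy as np
import pytest

from neurofluid import phantom as ph
from neurofluid.io_imaging import ASLParameters


@pytest.fixture(scope="session")
def atlas():
    return ph.build_tissue_atlas((64, 64, 28), seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    return ph.build_tissue_atlas((32, 32, 16), seed=1)


@pytest.fixture(scope="session")
def tissue_params():
    return ph.TissueParameters()


@pytest.fixture(scope="session")
def protocol():
    return ph.default_dwi_protocol()


@pytest.fixture(scope="session")
def asl_params():
    return ASLParameters()


@pytest.fixture(scope="session")
def noiseless_dwi(atlas, tissue_params, protocol):
    return ph.simulate_dwi_series(atlas, tissue_params, protocol, snr=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
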