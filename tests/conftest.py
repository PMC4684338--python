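import numpy as np
import pytest

from dcepk.protocol import AcquisitionProtocol
from dcepk.kinetics import AIF
from dcepk.synthetic import (
    DEFAULT_AIF,
    default_phantom_spec,
    evaluate_aif,
    generate_phantom,
    snr_to_sigma,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def t_grid(protocol):
    return protocol.t_grid()


@pytest.fixture(scope="session")
def cp_default(t_grid):
    return evaluate_aif(DEFAULT_AIF, t_grid)


@pytest.fixture(scope="session")
def aif_default(t_grid, cp_default):
    return AIF(t_grid=t_grid, cp=cp_default)


@pytest.fixture(scope="session")
def noiseless_phantom(protocol):
    return generate_phantom(default_phantom_spec(noise_sigma=0.0, seed=0), protocol)


@pytest.fixture(scope="session")
def snr50_phantom(protocol):
    """Phantom at SNR 50 on the pre-contrast tissue signal, 200-voxel region."""
    sigma = snr_to_sigma(50.0, 1100.0, 1000.0, protocol)
    spec = default_phantom_spec(grid_shape=(12, 12, 4), noise_sigma=sigma, seed=7)
    return generate_phantom(spec, protocol)
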