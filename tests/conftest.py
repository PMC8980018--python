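import numpy as np
import pytest

from engramap import DetectionParams, VolumeSpec, generate_volume


@pytest.fixture(scope="session")
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def small_volume():
    """A compact noisy volume with 8 known cells, shared across tests."""
    spec = VolumeSpec(shape=(48, 48, 16), n_cells=8, seed=42)
    vol, truth = generate_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noiseless_single_blob():
    spec = VolumeSpec(shape=(32, 32, 16), n_cells=1, background_sd=0.0, seed=7)
    vol, truth = generate_volume(spec)
    return spec, vol, truth
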