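import numpy as np
import pytest

from lamdiff import AcquisitionModel, BilayerModel

CONTRAST_FRACTIONS = [0.08, 0.20, 0.50, 1.00]


@pytest.fixture
def default_model() -> BilayerModel:
    """PC-like stacked bilayer: D = 50.4 A, headgroup peaks at +/-18.7 A."""
    return BilayerModel()


@pytest.fixture
def noiseless_acq() -> AcquisitionModel:
    return AcquisitionModel(noise_scale=0.0, background=(0.0,), seed=0)


@pytest.fixture
def noisy_acq() -> AcquisitionModel:
    return AcquisitionModel(noise_scale=1.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
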