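import numpy as np
import pytest

from holovol import OpticalConfig


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    """The reference acquisition geometry: 532 nm, 1.67 um pixels, 6x grid."""
    return OpticalConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hires_pitch(optics) -> float:
    return optics.highres_pitch
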