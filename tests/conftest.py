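import numpy as np
import pytest

from mea3d.core import StimProtocol
from mea3d.geometry import TissueSpec, build_standard_array
from mea3d.synth import SynthConfig


@pytest.fixture(scope="session")
def tissue():
    return TissueSpec()


@pytest.fixture(scope="session")
def layout(tissue):
    return build_standard_array(tissue)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """Desk-scale generator config for fast unit tests."""
    return SynthConfig(neurons_per_somatic_region=150, seed=3)


@pytest.fixture
def protocol():
    return StimProtocol()
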