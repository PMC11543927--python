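import numpy as np
import pytest

from boxbind.thermal_shift import ThermoModel


@pytest.fixture
def model():
    """Two-state model used throughout the thermal-shift tests."""
    return ThermoModel(tm0_K=318.15, dhu_kJmol=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
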