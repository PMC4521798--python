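import numpy as np
import pytest

from ratechaos import transfer as tr


@pytest.fixture(scope="session")
def sigmoid():
    return tr.sigmoid_erf()


@pytest.fixture(scope="session")
def tlin():
    return tr.threshold_linear()


@pytest.fixture(scope="session")
def lif_unit():
    """LIF transfer with tau_m = 1 (time measured in membrane constants)."""
    return tr.lif(1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
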