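import numpy as np
import pytest

from bequeathal import ModelParams

E_INV = float(np.exp(-1.0))


@pytest.fixture
def saturated():
    """No baseline or dispersal mortality: the habitat stays saturated (R=1)."""
    return ModelParams(s_A=1.0, s_J=1.0, d_A=1.0, d_J=1.0)


@pytest.fixture
def open_habitat():
    """25% baseline mortality in both classes, free dispersal."""
    return ModelParams(s_A=0.75, s_J=0.75, d_A=1.0, d_J=1.0)
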