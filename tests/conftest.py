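import numpy as np
import pytest

from crossmodal.observer import PsychometricFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer_pf():
    """A mid-range 2IFC observer used across modules."""
    return PsychometricFunction(alpha=-15.0, beta=2.0, lapse=0.02)
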