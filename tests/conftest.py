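import numpy as np
import pytest

from cplearn import build_peripheral
from cplearn.controller import ControllerParams
from cplearn.peripheral import PeripheralParams
from cplearn.stimuli import StimulusEncoder


@pytest.fixture(scope="session")
def small_peripheral():
    """A quickly fine-tuned peripheral shared by unit tests.

    Uses a reduced augmentation set; the readout still recovers the binary
    codings of all 8 clean stimuli.
    """
    params = PeripheralParams()
    encoder, state = build_peripheral(0, params, n_augment=128)
    return encoder, state, params


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def default_controller_params():
    return ControllerParams()
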