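import numpy as np
import pytest

from mcisim.stimuli import generate_test_set, generate_training_set


@pytest.fixture(scope="session")
def test_set():
    return generate_test_set()


@pytest.fixture(scope="session")
def training_set():
    return generate_training_set()


@pytest.fixture(scope="session")
def prepared_test_set(test_set):
    """Full signal chain (tracking, transposition, vocoding at 4 and 8
    channels, cue extraction) over the 54 test stimuli; shared because it is
    the expensive step."""
    from mcisim.experiment import prepare_stimuli

    return prepare_stimuli(test_set, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
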