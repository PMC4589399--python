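import numpy as np
import pytest

import petkin as pk


@pytest.fixture(scope="session")
def schedule():
    """The 29-frame mouse acquisition schedule (3093 s)."""
    return pk.mouse_dynamic_schedule()


@pytest.fixture(scope="session")
def bolus():
    return pk.default_mouse_bolus()


@pytest.fixture(scope="session")
def plasma_tac(schedule, bolus):
    """Frame-averaged plasma TAC of the default bolus."""
    return pk.frame_average(bolus, schedule)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
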