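import numpy as np
import pytest

from mapspread.behaviour import RingTask
from mapspread.network import run_full_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def task11():
    return RingTask(11)


# Full-protocol simulations are expensive (~30-40 s each); they are shared
# session-wide by every test that inspects probe outcomes.
PRE_SEEDS = (201, 202)
PLC_SEEDS = (201, 202, 203)
ATX_SEEDS = (201, 202, 203, 204, 205)


@pytest.fixture(scope="session")
def pre_results():
    return [run_full_protocol("pre", seed=s) for s in PRE_SEEDS]


@pytest.fixture(scope="session")
def plc_results():
    return [run_full_protocol("plc", seed=s) for s in PLC_SEEDS]


@pytest.fixture(scope="session")
def atx_results():
    return [run_full_protocol("atx", seed=s) for s in ATX_SEEDS]
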