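import numpy as np
import pytest
from hypothesis import settings

from relscale.data_model import DurationRecord, IPDTrial

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from relscale.datasets import MOSSAD, PETRUS
from relscale.synthetic_trials import TrialConfig, simulate_trial


def make_ipd(arm_a, arm_b, labels=("treated", "control"), censored_a=None,
             censored_b=None):
    """Build a tiny two-arm IPDTrial from plain lists."""
    ca = censored_a or [False] * len(arm_a)
    cb = censored_b or [False] * len(arm_b)
    records = [
        DurationRecord(float(v), labels[0], bool(c)) for v, c in zip(arm_a, ca)
    ] + [
        DurationRecord(float(v), labels[1], bool(c)) for v, c in zip(arm_b, cb)
    ]
    return IPDTrial(records=tuple(records), label="toy")


@pytest.fixture
def mossad():
    return MOSSAD


@pytest.fixture
def petrus():
    return PETRUS


@pytest.fixture(scope="session")
def multiplicative_ipd():
    """A moderately sized trial with a true 25% multiplicative reduction."""
    return simulate_trial(
        TrialConfig(seed=7, ratio=0.75, n_treated=50, n_control=50)
    ).ipd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
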