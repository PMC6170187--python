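import numpy as np
import pytest

from econochoice.synthetic_data import SessionParams, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_session():
    """A 220-trial session with a clear 2:1 preference, fixed seed."""
    params = SessionParams(
        true_log_ip=np.log(2.0), true_sigma=0.6,
        reps_per_offer_per_laser=10, seed=99,
    )
    return simulate_session(params)


def make_session(log_ip, sigma, reps=10, seed=0, **kwargs):
    params = SessionParams(
        true_log_ip=log_ip, true_sigma=sigma,
        reps_per_offer_per_laser=reps, seed=seed, **kwargs,
    )
    return simulate_session(params)
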