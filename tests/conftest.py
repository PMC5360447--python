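import dataclasses

import numpy as np
import pytest

import photoflex as pf


def yfp_variant(config: pf.SimConfig) -> pf.SimConfig:
    """Zero-neural (activity-insensitive fluorophore) version of a config."""
    neural = dataclasses.replace(
        config.neural,
        cs_amplitude={k: 0.0 for k in pf.US_IDENTITIES},
        us_gain=0.0,
        airpuff_us_amplitude=0.0,
    )
    return dataclasses.replace(config, neural=neural)


@pytest.fixture(scope="session")
def small_config():
    # one short session with a mid-session reversal; used by most unit tests
    return pf.SimConfig(
        n_sessions=1, trials_per_session=30, reversal_session=0, reversal_trial=15, seed=11
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return pf.generate_session(small_config)


@pytest.fixture(scope="session")
def processed_small(small_session):
    return pf.process_session(small_session)


@pytest.fixture(scope="session")
def expert_config():
    # session generated a day before the reversal: an "expert stage" session
    return pf.SimConfig(
        n_sessions=2, trials_per_session=40, reversal_session=1, reversal_trial=20, seed=7
    )


@pytest.fixture(scope="session")
def expert_session(expert_config):
    return pf.generate_session(expert_config, session_index=0)
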