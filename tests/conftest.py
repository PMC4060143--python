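import numpy as np
import pytest

from medisig import SyntheticConfig, generate_session
from medisig import preprocess as pp


@pytest.fixture(scope="session")
def short_config():
    return SyntheticConfig(duration=30.0, seed=1234)


@pytest.fixture(scope="session")
def session_pair(short_config):
    """One meditation and one control session of the same subject."""
    med = generate_session(short_config, "s01", "meditation")
    ctl = generate_session(short_config, "s01", "control")
    return {"meditation": med, "control": ctl}


@pytest.fixture(scope="session")
def clean_eeg(session_pair):
    return session_pair["control"][0]


@pytest.fixture(scope="session")
def prepped_eeg(clean_eeg):
    rec, mask = pp.preprocess_eeg_spectral(clean_eeg)
    return rec, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
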