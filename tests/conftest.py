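import numpy as np
import pytest
from hypothesis import settings

from painlfp.datatypes import SimConfig

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from painlfp.preprocess import preprocess_trialset
from painlfp.simulate import generate_trial_set


@pytest.fixture(scope="session")
def small_trialset():
    """Desk-scale three-class set, no artifacts (generated once per session)."""
    cfg = SimConfig(n_trials={"HN": 30, "NN": 30, "NS": 30}, seed=7, artifact_rate=0.0)
    return generate_trial_set(cfg)


@pytest.fixture(scope="session")
def clean_small(small_trialset):
    clean, _ = preprocess_trialset(small_trialset, do_reject=False)
    return clean


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
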