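import numpy as np
import pytest

from duomeg import synthgen as sg


@pytest.fixture(scope="session")
def default_pair():
    """One realized synthetic pair under the default study conditions."""
    cfg = sg.PairConfig(seed=1)
    rec_a, rec_b, gt = sg.gen_movement_pair(cfg)
    return cfg, rec_a, rec_b, gt


@pytest.fixture(scope="session")
def meg_pair(default_pair):
    """Gradiometer pair with 8 planted channels at snr=1, plus ground truth."""
    cfg, rec_a, rec_b, gt = default_pair
    planted = set(range(60, 68))
    ga, gb = sg.gen_meg_pair(cfg, rec_a, rec_b, planted, snr=1.0)
    return ga, gb, planted


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
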