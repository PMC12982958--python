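import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kneeprop import protocol
from kneeprop.protocol import GameEvent
from kneeprop.simulate import ParticipantProfile, default_synergy_truth, gen_emg

# sklearn's NMF warns about reaching max_iter on deliberately hard fits
warnings.filterwarnings("ignore", message=".*Maximum number of iterations.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile():
    return ParticipantProfile(id="P01", group="EG", error_bias=5.0,
                              error_sd=3.0, learning_gain=0.5, seed=7)


@pytest.fixture
def squat_schedule():
    return protocol.test_schedule("pretest_squat", rng_seed=11)


@pytest.fixture
def stretch_schedule():
    return protocol.test_schedule("pretest_stretch", rng_seed=12)


@pytest.fixture
def fish_events():
    """A handful of catches, enough to anchor synergy bursts."""
    return [GameEvent(t=2.0 + 3.0 * i, kind="fish_caught", trail=i % 4) for i in range(4)]


@pytest.fixture
def rank3_emg(fish_events):
    """Noise-free rank-3 synergy mixture at the default EMG rate."""
    truth = default_synergy_truth(k=3, noise_sd=0.0)
    emg = gen_emg(fish_events, truth, fs=1111.0, duration=13.0,
                  rng=np.random.default_rng(0))
    return emg, truth
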