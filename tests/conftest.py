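import hypothesis
import numpy as np
import pytest

import followerkit as fk

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def template10():
    """Default 1-AP transient sampled at 10 Hz."""
    return fk.make_template(0.06, 0.4, 10.0)


@pytest.fixture(scope="session")
def short_schedule():
    """20 trials with the standard 0.5 s pulse / 2.5 s gap layout."""
    return fk.make_schedule(n_trials=20)


@pytest.fixture(scope="session")
def sparse_schedule():
    """Few trials with long gaps, so transient tails from one trial decay
    below numerical precision before the next trial's baseline window."""
    return fk.make_schedule(n_trials=5, pulse_s=0.5, gap_s=15.0)


@pytest.fixture
def noiseless_config():
    return fk.SynthConfig(
        n_cells=3, spont_event_rate=0.0, noise_sd=0.0, duration=None
    )


@pytest.fixture(scope="session")
def small_fov(short_schedule):
    """4-cell sham recording with default generator settings."""
    return fk.simulate_fov(fk.SynthConfig(n_cells=4), short_schedule, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
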