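import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cuecode as cc

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """50 trials per block: fast but large enough for every invariant."""
    return cc.SessionConfig(n_trials_per_block=50, rng_seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    """One simulated session with a mixed 10-unit population."""
    rng = np.random.default_rng(11)
    tuning = cc.make_tuning_population(10, rng, fsi_fraction=0.2)
    trials, spiketrains = cc.simulate_session(small_config, tuning, rng)
    return trials, spiketrains


@pytest.fixture(scope="session")
def default_session():
    """Full-size session (100 trials per block), 12 units."""
    config = cc.SessionConfig(rng_seed=21)
    rng = np.random.default_rng(21)
    tuning = cc.make_tuning_population(12, rng)
    trials, spiketrains = cc.simulate_session(config, tuning, rng)
    return trials, spiketrains, config


def spikes_from_window_counts(trials, counts, window, rng):
    """Spike train with ``counts[i]`` spikes uniform in trial i's window.

    Helper for calibration tests that need exact per-window counts without
    paying for full-session generation.
    """
    events = trials["t_cue_onset"].to_numpy()
    lo, hi = window
    starts = np.repeat(events + lo, counts)
    times = starts + rng.random(starts.size) * (hi - lo)
    return np.sort(times)
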