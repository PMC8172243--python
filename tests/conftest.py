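import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import photoscratch as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One full-scale synthetic session (default noise/motion) shared across tests."""
    cfg = ps.SimConfig(seed=7, duration_s=300.0)
    events = ps.simulate_events(cfg)
    rec, truth = ps.simulate_session(cfg, events)
    return cfg, events, rec, truth


@pytest.fixture(scope="session")
def demodulated(default_session):
    _, _, rec, _ = default_session
    return ps.demodulate_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_event_train(rng, duration_s=600.0, max_events=40) -> ps.EventTrain:
    n = int(rng.integers(0, max_events))
    onsets = np.sort(rng.uniform(0, duration_s, size=n))
    onsets = np.unique(onsets)
    return ps.EventTrain(onsets_s=onsets, session_duration_s=duration_s)


def bout_union_oracle(onsets: np.ndarray, window_s: float):
    """Brute-force oracle: pad each event to [t, t+window], take the interval
    union, and read bouts off the connected components."""
    bouts = []
    for t in onsets:
        if bouts and t <= bouts[-1][1]:
            bouts[-1][1] = t + window_s
            bouts[-1][2] += 1
            bouts[-1][3] = t
        else:
            bouts.append([t, t + window_s, 1, t])
    # (onset, last-member onset, count)
    return [(b[0], b[3], b[2]) for b in bouts]
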