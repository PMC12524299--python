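import numpy as np
import pytest
from hypothesis import settings

import tdsliking as tk

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return tk.StudyDesign()


@pytest.fixture(scope="session")
def profiles():
    return tk.default_profiles()


@pytest.fixture(scope="session")
def conditions(design):
    return {c.condition_id: c for c in design.conditions}


@pytest.fixture(scope="session")
def small_dataset():
    """Default-profile bootstrap dataset at reduced replicate count (B=10)."""
    replicates, conditions, panelists = tk.default_dataset(seed=11, n_replicates=10)
    return replicates, conditions, panelists


@pytest.fixture(scope="session")
def panel_session(design, profiles):
    """One full synthetic session at the default study scale."""
    return tk.generate_session(design, profiles, seed=5)


def random_tds_trial(rng, n_events=6, duration=12.0, panelist="p01", condition="plain"):
    times = np.sort(rng.uniform(0.05, duration - 0.05, size=n_events))
    while len(np.unique(times)) < n_events:
        times = np.sort(rng.uniform(0.05, duration - 0.05, size=n_events))
    attrs = rng.choice(tk.ATTRIBUTES, size=n_events)
    events, last = [], None
    for t, a in zip(times, attrs):
        if a != last:
            events.append((float(t), str(a)))
            last = a
    return tk.TrialRecord(panelist, condition, "TDS", 1, duration, tuple(events))


def random_tl_trial(rng, n_events=8, duration=12.0, panelist="p01", condition="plain"):
    times = np.sort(rng.uniform(0.05, duration - 0.05, size=n_events))
    vals = rng.integers(1, 10, size=n_events)
    events = tuple((float(t), int(v)) for t, v in zip(times, vals))
    return tk.TrialRecord(panelist, condition, "TL", 1, duration, events)
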