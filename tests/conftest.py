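import numpy as np
import pandas as pd
import pytest

from motifnet.session import Session, validate_trials
from motifnet.simulate import SimConfig, generate_session


def make_trials(n_trials=8, trial_len=60, frame_rate=9.35, sides=None,
                choices=None):
    if sides is None:
        sides = ["L", "R"] * (n_trials // 2 + 1)
    sides = list(sides)[:n_trials]
    if choices is None:
        choices = sides
    choices = list(choices)[:n_trials]
    stim_on = np.arange(n_trials) * trial_len + 19
    go = stim_on + 28
    resp = go + 3
    return validate_trials(pd.DataFrame({
        "stimulus_side": sides,
        "choice_side": choices,
        "correct": [s == c for s, c in zip(sides, choices)],
        "rewarded": [s == c for s, c in zip(sides, choices)],
        "stimulus_onset_frame": stim_on,
        "go_cue_frame": go,
        "response_frame": resp,
        "distractor": False,
    }))


def make_session(n_neurons=6, n_trials=8, seed=0, activity=None,
                 regions=None, frame_rate=9.35):
    trials = make_trials(n_trials)
    n_frames = int(trials["go_cue_frame"].iloc[-1]) + 20
    rng = np.random.default_rng(seed)
    if activity is None:
        activity = rng.poisson(0.3, size=(n_neurons, n_frames)).astype(float)
    if regions is None:
        regions = np.array(["ALM"] * (n_neurons // 2) + ["PPC"] * (n_neurons - n_neurons // 2),
                           dtype=object)
    return Session(
        activity=activity,
        frame_rate=frame_rate,
        neuron_ids=np.arange(n_neurons),
        regions=np.asarray(regions, dtype=object),
        trials=trials,
    )


@pytest.fixture
def small_session():
    return make_session()


@pytest.fixture(scope="session")
def sim_session():
    """A modest synthetic session with planted structure, shared across
    tests (generation is cheap; GLM fits on it are not, so tests that
    fit keep their own scope small)."""
    cfg = SimConfig(n_neurons_per_region=12, n_trials=60, response_s=1.5,
                    coupling_density=0.12, tuning_snr=1.2, seed=11)
    return generate_session(cfg, seed=11)
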