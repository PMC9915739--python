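import numpy as np
import pytest

import mesoframe as mf


def make_session(seed: int, duration: float = 480.0, p_alternate: float = 0.5,
                 **kwargs):
    """Simulate one Y-maze session and derive trials and position bins."""
    cfg = mf.BehaviorSimConfig(p_alternate=p_alternate,
                               session_duration=duration, seed=seed, **kwargs)
    arms, truth = mf.simulate_arm_entries(cfg)
    traj = mf.simulate_trajectory(arms, cfg)
    entries = mf.detect_arm_entries(traj)
    trials, n_aborted = mf.segment_trials(traj, entries)
    bins = mf.trial_bins(traj, trials)
    return {
        "cfg": cfg, "arms": arms, "truth": truth, "traj": traj,
        "entries": entries, "trials": trials, "bins": bins,
        "n_aborted": n_aborted,
    }


@pytest.fixture(scope="session")
def short_session():
    """A standard 8-min session shared across tests."""
    return make_session(seed=3)


@pytest.fixture(scope="session")
def long_session():
    """A longer recording (three session-lengths) for ensemble statistics."""
    return make_session(seed=7, duration=1440.0)
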