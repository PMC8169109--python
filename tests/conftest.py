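import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dmsephys import (BehaviorGenConfig, Session, TaskConfig, Trial,
                      UnitGenConfig, simulate_session, simulate_unit)


@pytest.fixture
def task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture
def balanced_session() -> Session:
    """Deterministic 60+60-trial session for spike-train fixtures."""
    cfg = BehaviorGenConfig(n_match_trials=60, n_nonmatch_trials=60,
                            p_hit=0.9, p_fa=0.3, seed=11)
    return simulate_session(cfg)


def make_trial(is_match: bool, licks, trial_id: int = 0,
               sample: float = 3000.0, delay: float = 1.5,
               laser=None) -> Trial:
    if is_match:
        test = sample
    else:
        test = 12000.0 if sample == 3000.0 else 3000.0
    return Trial(trial_id=trial_id, sample_stimulus=sample, test_stimulus=test,
                 is_match=is_match, delay_duration=delay,
                 lick_times=np.asarray(licks, dtype=float), laser_window=laser)


@pytest.fixture
def selective_unit(balanced_session):
    cfg = UnitGenConfig(r0=4.0, a_pref=20.0, a_nonpref=5.0, seed=21)
    return simulate_unit(cfg, balanced_session, unit_id="sel-0")


@pytest.fixture
def null_unit(balanced_session):
    cfg = UnitGenConfig(r0=6.0, a_pref=10.0, a_nonpref=10.0, seed=22)
    return simulate_unit(cfg, balanced_session, unit_id="null-0")
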