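from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from stakestep.task import (
    ACTIONS,
    PLANETS,
    Session,
    TaskConfig,
    TrialRecord,
    deliver_reward,
    transition,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture()
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture()
def small_config() -> TaskConfig:
    return TaskConfig(n_trials=20)


def make_random_session(
    n_trials: int,
    seed: int,
    config: TaskConfig | None = None,
    subject_id: str = "rand",
    group: str = "unknown",
) -> Session:
    """A session with uniformly random choices/stakes/rewards; used to probe
    likelihoods on arbitrary observed data."""
    config = config or TaskConfig(n_trials=n_trials)
    config = config.replace(n_trials=n_trials)
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        stake = "high" if rng.random() < config.p_high_stake else "low"
        s1 = int(rng.integers(1, 3))
        action = ACTIONS[int(rng.integers(2))]
        planet = transition(s1, action, config)
        base = float(rng.integers(0, 10))
        trials.append(
            TrialRecord(
                trial_index=t,
                stake=stake,
                start_state=s1,
                action=action,
                response_key="left" if action == "A" else "right",
                planet=planet,
                base_reward=base,
                delivered_reward=deliver_reward(base, stake, config),
            )
        )
    return Session(
        subject_id=subject_id, group=group, config=config, trials=trials
    )
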