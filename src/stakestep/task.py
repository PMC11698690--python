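"""Generative environment for the stakes-modulated two-step task.

Each trial begins with a stake cue (low, or high: second-stage rewards are
multiplied by ``stake_multiplier``), then starts in one of two first-stage
states.  Both states offer the same choice between two spaceships that travel
to a red or a purple planet, where a drifting number of points is paid out.
Because the two start states are equivalent in outcome, an agent that plans
through the transition structure can transfer what it learns in one state to
the other, while a purely habit-driven agent cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

STATES = (1, 2)
ACTIONS = ("A", "B")
PLANETS = ("red", "purple")
STAKES = ("low", "high")
KEYS = ("left", "right")
GROUPS = ("user", "nonuser", "unknown")

ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}
PLANET_INDEX = {p: i for i, p in enumerate(PLANETS)}
STAKE_INDEX = {s: i for i, s in enumerate(STAKES)}
KEY_INDEX = {k: i for i, k in enumerate(KEYS)}

#: Each spaceship always reaches one fixed planet (deterministic transitions);
#: both start states map action A to red and action B to purple.
DEFAULT_TRANSITION_MAP: dict[str, dict[str, str]] = {
    "1": {"A": "red", "B": "purple"},
    "2": {"A": "red", "B": "purple"},
}


class ConfigError(ValueError):
    """Invalid task or pipeline configuration."""


class ProtocolError(RuntimeError):
    """A policy violated the task protocol (e.g. returned an unknown action)."""


def _canonical_transitions(raw: Mapping) -> dict[str, dict[str, dict[str, float]]]:
    """Normalise a transition map to {state: {action: {planet: prob}}}.

    Accepts deterministic entries (planet name) or stochastic entries
    (mapping planet -> probability).
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for s in STATES:
        key = str(s)
        if key not in raw and s not in raw:
            raise ConfigError(f"transition_map missing state {s}")
        row = raw.get(key, raw.get(s))
        out[key] = {}
        for a in ACTIONS:
            if a not in row:
                raise ConfigError(f"transition_map missing action {a} in state {s}")
            entry = row[a]
            if isinstance(entry, str):
                if entry not in PLANETS:
                    raise ConfigError(f"unknown planet {entry!r} in transition_map")
                probs = {p: (1.0 if p == entry else 0.0) for p in PLANETS}
            else:
                probs = {p: float(entry.get(p, 0.0)) for p in PLANETS}
                if any(v < 0 for v in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ConfigError(
                        f"transition probabilities for state {s}, action {a} "
                        "must be non-negative and sum to 1"
                    )
            out[key][a] = probs
        # the two actions must (modally) reach the two distinct planets
        modal = [max(out[key][a], key=out[key][a].get) for a in ACTIONS]
        if modal[0] == modal[1]:
            raise ConfigError(
                f"state {s}: both actions modally reach {modal[0]!r}; the two "
                "actions must cover the red and the purple planet"
            )
    return out


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task environment.

    Defaults reproduce the study design: 200 trials, 50/50 low/high stake
    cues, 5x reward magnification on high stakes, payoffs drifting on
    [0, 9] points with step SD 2.0, deterministic spaceship -> planet
    transitions, and a fair coin over the two start states.
    """

    n_trials: int = 200
    p_high_stake: float = 0.5
    stake_multiplier: int = 5
    payoff_min: float = 0.0
    payoff_max: float = 9.0
    drift_sd: float = 2.0
    transition_map: Mapping = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_TRANSITION_MAP))
    )
    p_start_state: float = 0.5
    seed: int = 0
    integer_payoffs: bool = True
    learn_from_delivered: bool = False
    shuffle_keys: bool = False

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ConfigError("n_trials must be >= 0")
        if not 0.0 <= self.p_high_stake <= 1.0:
            raise ConfigError("p_high_stake must lie in [0, 1]")
        if not 0.0 <= self.p_start_state <= 1.0:
            raise ConfigError("p_start_state must lie in [0, 1]")
        if self.stake_multiplier < 1:
            raise ConfigError("stake_multiplier must be a positive integer")
        if self.payoff_min >= self.payoff_max:
            raise ConfigError("payoff_min must be < payoff_max")
        if self.drift_sd < 0:
            raise ConfigError("drift_sd must be >= 0")
        object.__setattr__(
            self, "transition_map", _canonical_transitions(self.transition_map)
        )

    # --- transition structure -------------------------------------------------

    def transition_probs(self) -> np.ndarray:
        """P(planet | state, action) as a (2 states, 2 actions, 2 planets) array."""
        P = np.zeros((2, 2, 2))
        for si, s in enumerate(STATES):
            for ai, a in enumerate(ACTIONS):
                for pi, p in enumerate(PLANETS):
                    P[si, ai, pi] = self.transition_map[str(s)][a][p]
        return P

    def modal_planets(self) -> np.ndarray:
        """Most likely planet index per (state, action); the planet itself
        under the deterministic default."""
        return np.argmax(self.transition_probs(), axis=2)

    # --- serialization --------------------------------------------------------

    _FIELDS = (
        "n_trials", "p_high_stake", "stake_multiplier", "payoff_min",
        "payoff_max", "drift_sd", "transition_map", "p_start_state", "seed",
        "integer_payoffs", "learn_from_delivered", "shuffle_keys",
    )

    def to_json(self) -> str:
        return json.dumps({f: getattr(self, f) for f in self._FIELDS}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        doc = json.loads(text)
        unknown = set(doc) - set(cls._FIELDS)
        if unknown:
            raise ConfigError(f"unknown TaskConfig keys: {sorted(unknown)}")
        return cls(**doc)

    def replace(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RewardWalk:
    """Per-planet payoff series (points), one value per trial and planet."""

    payoffs: np.ndarray  # shape (n_trials, 2), columns ordered as PLANETS

    def series(self, planet: str) -> np.ndarray:
        return self.payoffs[:, PLANET_INDEX[planet]]


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    stake: str
    start_state: int
    action: str
    response_key: str
    planet: str
    base_reward: float
    delivered_reward: float

    def __post_init__(self) -> None:
        if self.stake not in STAKES:
            raise ValueError(f"unknown stake {self.stake!r}")
        if self.start_state not in STATES:
            raise ValueError(f"unknown start state {self.start_state!r}")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.response_key not in KEYS:
            raise ValueError(f"unknown response key {self.response_key!r}")
        if self.planet not in PLANETS:
            raise ValueError(f"unknown planet {self.planet!r}")


@dataclass
class Session:
    """One subject's ordered trial records plus the generating configuration."""

    subject_id: str
    group: str
    config: TaskConfig
    trials: list[TrialRecord]
    true_params: dict | None = None

    def __len__(self) -> int:
        return len(self.trials)


def validate_session(session: Session) -> None:
    """Check every trial-level invariant; raise ValueError on the first breach."""
    if session.group not in GROUPS:
        raise ValueError(f"unknown group {session.group!r}")
    cfg = session.config
    for i, tr in enumerate(session.trials):
        if tr.trial_index != i:
            raise ValueError(
                f"trial indices not consecutive: expected {i}, got {tr.trial_index}"
            )
        mult = cfg.stake_multiplier if tr.stake == "high" else 1
        if abs(tr.delivered_reward - tr.base_reward * mult) > 1e-9:
            raise ValueError(
                f"trial {i}: delivered_reward {tr.delivered_reward} != "
                f"base_reward x stake multiplier"
            )
        if cfg.transition_map[str(tr.start_state)][tr.action][tr.planet] <= 0:
            raise ValueError(
                f"trial {i}: planet {tr.planet!r} unreachable from "
                f"(state {tr.start_state}, action {tr.action})"
            )


# --- generative pieces --------------------------------------------------------


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] (reflecting boundaries)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def generate_reward_walks(
    config: TaskConfig, seed: int, init: Sequence[float] | None = None
) -> RewardWalk:
    """Two independent Gaussian random walks with reflecting boundaries.

    ``init`` optionally fixes the starting payoff of (red, purple);
    by default each planet starts uniformly inside the payoff bounds.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.payoff_min, config.payoff_max
    if init is None:
        start = rng.uniform(lo, hi, size=2)
    else:
        start = np.asarray(init, dtype=float)
        if start.shape != (2,) or np.any(start < lo) or np.any(start > hi):
            raise ConfigError("init must be two payoffs within the payoff bounds")
    out = np.empty((config.n_trials, 2))
    x = start.copy()
    for t in range(config.n_trials):
        out[t] = x
        x = _reflect(x + rng.normal(0.0, config.drift_sd, size=2), lo, hi)
    if config.integer_payoffs:
        out = np.rint(out)
    return RewardWalk(payoffs=out)


def sample_stake_sequence(config: TaskConfig, seed: int) -> list[str]:
    """Independent stake cues, high with probability ``p_high_stake``."""
    rng = np.random.default_rng(seed)
    draws = rng.random(config.n_trials) < config.p_high_stake
    return ["high" if d else "low" for d in draws]


def transition(start_state: int, action: str, config: TaskConfig) -> str:
    """Deterministic planet lookup (the modal planet for stochastic maps)."""
    if start_state not in STATES:
        raise ValueError(f"unknown start state {start_state!r}")
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    row = config.transition_map[str(start_state)][action]
    return max(row, key=row.get)


def deliver_reward(base_reward: float, stake: str, config: TaskConfig) -> float:
    if stake not in STAKES:
        raise ValueError(f"unknown stake {stake!r}")
    return base_reward * (config.stake_multiplier if stake == "high" else 1)


# --- playing a policy through the task ---------------------------------------


@dataclass(frozen=True)
class TrialObservation:
    """What the agent sees before choosing: the cue, the start state and the
    on-screen layout mapping each action to (planet it modally reaches, key)."""

    trial_index: int
    stake: str
    start_state: int
    layout: dict[str, tuple[str, str]]


@runtime_checkable
class Policy(Protocol):
    def choose(self, obs: TrialObservation, rng: np.random.Generator) -> str: ...

    def observe(self, record: TrialRecord) -> None: ...


class _CallablePolicy:
    def __init__(self, fn: Callable):
        self._fn = fn

    def choose(self, obs: TrialObservation, rng: np.random.Generator) -> str:
        return self._fn(obs, rng)

    def observe(self, record: TrialRecord) -> None:
        pass


class UniformRandomPolicy:
    """Chooses each spaceship with probability 1/2; learns nothing."""

    def choose(self, obs: TrialObservation, rng: np.random.Generator) -> str:
        return ACTIONS[int(rng.integers(2))]

    def observe(self, record: TrialRecord) -> None:
        pass


def build_session(
    config: TaskConfig,
    policy,
    seed: int,
    subject_id: str = "sim",
    group: str = "unknown",
    true_params: dict | None = None,
    walks: RewardWalk | None = None,
) -> Session:
    """Play ``policy`` through the environment for ``config.n_trials`` trials.

    All randomness (stake cues, start states, payoff walks, any key
    shuffling, stochastic transitions and the policy's own sampling) derives
    from ``seed``.  ``walks`` may inject a fixed payoff schedule.
    """
    if not isinstance(policy, Policy):
        policy = _CallablePolicy(policy)
    ss = np.random.SeedSequence(seed)
    s_stake, s_start, s_walk, s_env, s_agent = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    stakes = sample_stake_sequence(config, s_stake)
    starts_rng = np.random.default_rng(s_start)
    starts = np.where(starts_rng.random(config.n_trials) < config.p_start_state, 1, 2)
    if walks is None:
        walks = generate_reward_walks(config, s_walk)
    env_rng = np.random.default_rng(s_env)
    agent_rng = np.random.default_rng(s_agent)
    P = config.transition_probs()

    trials: list[TrialRecord] = []
    for t in range(config.n_trials):
        s1 = int(starts[t])
        if config.shuffle_keys and env_rng.random() < 0.5:
            keys = {"A": "right", "B": "left"}
        else:
            keys = {"A": "left", "B": "right"}
        layout = {
            a: (transition(s1, a, config), keys[a]) for a in ACTIONS
        }
        obs = TrialObservation(trial_index=t, stake=stakes[t], start_state=s1, layout=layout)
        action = policy.choose(obs, agent_rng)
        if action not in ACTIONS:
            raise ProtocolError(
                f"policy returned invalid action {action!r} on trial {t}"
            )
        probs = P[s1 - 1, ACTION_INDEX[action]]
        planet = PLANETS[int(env_rng.choice(2, p=probs))]
        base = float(walks.payoffs[t, PLANET_INDEX[planet]])
        record = TrialRecord(
            trial_index=t,
            stake=stakes[t],
            start_state=s1,
            action=action,
            response_key=keys[action],
            planet=planet,
            base_reward=base,
            delivered_reward=deliver_reward(base, stakes[t], config),
        )
        trials.append(record)
        policy.observe(record)
    return Session(
        subject_id=subject_id,
        group=group,
        config=config,
        trials=trials,
        true_params=dict(true_params) if true_params else None,
    )


def session_arrays(session: Session) -> dict[str, np.ndarray]:
    """Integer/float encodings of a session for the fast likelihood kernels.

    ``key_a`` is the physical key of action A on each trial (derivable from
    the chosen action's key because the two actions share the two keys).
    ``reward`` follows the session's learning-signal convention: the base
    payoff by default, the delivered (multiplied) payoff when the config sets
    ``learn_from_delivered``.
    """
    n = len(session.trials)
    out = {
        "stake": np.empty(n, dtype=np.int64),
        "s1": np.empty(n, dtype=np.int64),
        "a1": np.empty(n, dtype=np.int64),
        "planet": np.empty(n, dtype=np.int64),
        "key_a": np.empty(n, dtype=np.int64),
        "reward": np.empty(n, dtype=np.float64),
    }
    for t, tr in enumerate(session.trials):
        out["stake"][t] = STAKE_INDEX[tr.stake]
        out["s1"][t] = tr.start_state - 1
        a = ACTION_INDEX[tr.action]
        out["a1"][t] = a
        out["planet"][t] = PLANET_INDEX[tr.planet]
        k = KEY_INDEX[tr.response_key]
        out["key_a"][t] = k if a == 0 else 1 - k
        out["reward"][t] = (
            tr.delivered_reward if session.config.learn_from_delivered else tr.base_reward
        )
    return out
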