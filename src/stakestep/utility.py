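"""Risk-sensitive utility model and its genetic-algorithm fitter.

The model values each first-stage state-action pair by a mean-variance
utility U(s,a) = R(s,a) - mu * sign(R(s,a)) * sqrt(h(s,a)), where R is a
TD-learned expected return and h a running estimate of the return variance
(the risk).  Positive mu penalises variance on gains (risk aversion);
negative mu rewards it (risk seeking).  Five parameters are estimated —
mu, the softmax inverse temperature beta_u, the learning rate eta, the
discount factor Gamma and the TD-error cap delta_limit — by a real-valued
genetic algorithm maximizing the choice log-likelihood, fitted separately
for low- and high-stake trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._fastcore import utility_loglik
from .results import FitResult
from .task import (
    ACTIONS,
    ACTION_INDEX,
    PLANET_INDEX,
    Session,
    TaskConfig,
    TrialRecord,
    build_session,
    session_arrays,
)

PARAM_NAMES = ("mu", "beta_u", "eta", "gamma_disc", "delta_limit")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu": (-2.0, 2.0),
    "beta_u": (0.0, 10.0),
    "eta": (0.0, 1.0),
    "gamma_disc": (0.0, 1.0),
    "delta_limit": (0.1, 10.0),
}


@dataclass(frozen=True)
class UtilityParams:
    mu: float
    beta_u: float
    eta: float
    gamma_disc: float
    delta_limit: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(getattr(self, n)) for n in PARAM_NAMES):
            raise ValueError("all utility parameters must be finite")
        if self.beta_u < 0:
            raise ValueError("beta_u must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if not 0.0 <= self.gamma_disc <= 1.0:
            raise ValueError("gamma_disc must lie in [0, 1]")
        if self.delta_limit <= 0:
            raise ValueError("delta_limit must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass
class UtilityState:
    """Expected returns for the four first-stage pairs (``r1``) and the two
    planets (``r2``), plus the first-stage risk table ``h`` (variance units)."""

    r1: np.ndarray
    r2: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls) -> "UtilityState":
        return cls(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)))

    def copy(self) -> "UtilityState":
        return UtilityState(self.r1.copy(), self.r2.copy(), self.h.copy())


def utility(r_value, h_value, mu: float):
    """U = R - mu * sign(R) * sqrt(h), with sign(0) = 0."""
    r = np.asarray(r_value, dtype=float)
    h = np.asarray(h_value, dtype=float)
    if np.any(h < 0):
        raise ValueError("risk h must be non-negative")
    out = r - mu * np.sign(r) * np.sqrt(h)
    return float(out) if out.ndim == 0 else out


def _clip(x: float, limit: float) -> float:
    return max(-limit, min(limit, x))


def utility_update(
    state: UtilityState,
    trial: TrialRecord,
    params: UtilityParams,
    learning_reward: float | None = None,
) -> UtilityState:
    """One trial of return/risk learning.

    Stage 1: delta1 = Gamma * R(planet) - R(s1, a1), clipped at
    +/- delta_limit, moves the first-stage return.  Stage 2:
    delta2 = r - R(planet), clipped, moves the planet return.  The risk of
    the first-stage pair tracks the squared total first-stage error
    delta_eff = clip(delta1) + Gamma * clip(delta2) through the risk
    prediction error xi = delta_eff^2 - h (risk is estimated for
    first-stage pairs only).
    """
    if learning_reward is None:
        learning_reward = trial.base_reward
    eta, gam, dlim = params.eta, params.gamma_disc, params.delta_limit
    out = state.copy()
    s = trial.start_state - 1
    a = ACTION_INDEX[trial.action]
    pl = PLANET_INDEX[trial.planet]

    d1 = _clip(gam * out.r2[pl] - out.r1[s, a], dlim)
    out.r1[s, a] += eta * d1
    d2 = _clip(learning_reward - out.r2[pl], dlim)
    out.r2[pl] += eta * d2
    de = d1 + gam * d2
    out.h[s, a] += eta * (de * de - out.h[s, a])
    return out


def utility_choice_probabilities(
    state: UtilityState, start_state: int, params: UtilityParams
) -> np.ndarray:
    """Softmax over the two first-stage actions, p(a) prop. exp(beta_u * U(s,a))."""
    s = start_state - 1
    u = utility(state.r1[s], state.h[s], params.mu)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite utilities")
    logits = params.beta_u * u
    m = logits.max()
    ex = np.exp(logits - m)
    return ex / ex.sum()


def _include_mask(session: Session, stake_filter: str) -> np.ndarray:
    if stake_filter not in ("low", "high", "all"):
        raise ValueError(f"unknown stake filter {stake_filter!r}")
    return np.array(
        [
            1 if (stake_filter == "all" or tr.stake == stake_filter) else 0
            for tr in session.trials
        ],
        dtype=np.int64,
    )


def utility_log_likelihood(
    params: UtilityParams, session: Session, stake_filter: str = "all"
) -> float:
    """Log-likelihood of observed first-stage choices on the filtered trials.

    Learning always runs over every trial in order; the filter only selects
    which trials' choice probabilities enter the sum.
    """
    arr = session_arrays(session)
    inc = _include_mask(session, stake_filter)
    return float(
        utility_loglik(
            arr["s1"], arr["a1"], arr["planet"], arr["reward"], inc,
            params.mu, params.beta_u, params.eta, params.gamma_disc,
            params.delta_limit,
        )
    )


# --------------------------------------------------------------------------
# Genetic-algorithm fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    """Real-valued GA settings; the study-scale defaults are population 1000
    over 100 generations."""

    pop_size: int = 1000
    n_generations: int = 100
    crossover_rate: float = 0.5
    mutation_sd: Mapping[str, float] | None = None  # default: 10% of bound width
    elite_count: int = 5
    tournament_size: int = 3
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.n_generations < 1:
            raise ValueError("pop_size and n_generations must be >= 1")
        if not 1 <= self.elite_count <= self.pop_size:
            raise ValueError("need pop_size >= elite_count >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if lo >= hi:
                raise ValueError(f"degenerate bounds for {name}: [{lo}, {hi}]")

    def sds(self) -> np.ndarray:
        if self.mutation_sd is None:
            return np.array(
                [0.1 * (self.bounds[n][1] - self.bounds[n][0]) for n in PARAM_NAMES]
            )
        return np.array([float(self.mutation_sd[n]) for n in PARAM_NAMES])


def fit_ga(session: Session, stake_filter: str = "all", ga: GAConfig | None = None) -> FitResult:
    """Evolve utility-parameter vectors to maximize the choice log-likelihood.

    Tournament selection, uniform crossover, Gaussian mutation clipped to the
    parameter bounds, elitism; the best individual ever evaluated is
    returned.  Deterministic given ``ga.seed``.
    """
    ga = ga or GAConfig()
    rng = np.random.default_rng(ga.seed)
    lo = np.array([ga.bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([ga.bounds[n][1] for n in PARAM_NAMES])
    sds = ga.sds()
    arr = session_arrays(session)
    inc = _include_mask(session, stake_filter)

    def fitness(x: np.ndarray) -> float:
        return float(
            utility_loglik(
                arr["s1"], arr["a1"], arr["planet"], arr["reward"], inc,
                x[0], x[1], x[2], x[3], x[4],
            )
        )

    pop = rng.uniform(lo, hi, size=(ga.pop_size, len(PARAM_NAMES)))
    fits = np.array([fitness(ind) for ind in pop])
    best_x = pop[int(np.argmax(fits))].copy()
    best_f = float(np.max(fits))
    best_gen = 0
    history = [float(np.max(fits))]

    for gen in range(1, ga.n_generations + 1):
        order = np.argsort(-fits, kind="stable")
        elites = pop[order[: ga.elite_count]].copy()
        n_children = ga.pop_size - ga.elite_count
        children = np.empty((n_children, len(PARAM_NAMES)))
        for c in range(n_children):
            # tournament selection of two parents
            idx1 = rng.integers(0, ga.pop_size, size=ga.tournament_size)
            idx2 = rng.integers(0, ga.pop_size, size=ga.tournament_size)
            p1 = pop[idx1[np.argmax(fits[idx1])]]
            p2 = pop[idx2[np.argmax(fits[idx2])]]
            if rng.random() < ga.crossover_rate:
                mask = rng.random(len(PARAM_NAMES)) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            child = child + rng.normal(0.0, 1.0, size=len(PARAM_NAMES)) * sds
            children[c] = np.clip(child, lo, hi)
        pop = np.vstack([elites, children]) if n_children else elites
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = float(np.max(fits))
        history.append(gen_best)
        if gen_best > best_f:
            best_f = gen_best
            best_x = pop[int(np.argmax(fits))].copy()
            best_gen = gen

    estimates = {n: float(v) for n, v in zip(PARAM_NAMES, best_x)}
    return FitResult(
        model=f"utility_{stake_filter}",
        estimates=estimates,
        log_likelihood=best_f,
        log_posterior=best_f,
        n_restarts_run=ga.n_generations,
        best_restart=best_gen,
        converged=True,
        seed=ga.seed,
        extra={"best_fitness_per_generation": history},
    )


# --------------------------------------------------------------------------
# Generative use
# --------------------------------------------------------------------------


class UtilityAgent:
    """Plays the utility model through the task; optionally stake-conditional
    (separate parameter sets on low- and high-stake trials over one shared
    return/risk state)."""

    def __init__(
        self,
        params: UtilityParams,
        config: TaskConfig,
        params_high: UtilityParams | None = None,
    ):
        self.params_low = params
        self.params_high = params_high or params
        self.config = config
        self.state = UtilityState.zeros()

    def _params(self, stake: str) -> UtilityParams:
        return self.params_high if stake == "high" else self.params_low

    def choose(self, obs, rng: np.random.Generator) -> str:
        probs = utility_choice_probabilities(
            self.state, obs.start_state, self._params(obs.stake)
        )
        return ACTIONS[int(rng.choice(2, p=probs))]

    def observe(self, record: TrialRecord) -> None:
        lr = (
            record.delivered_reward
            if self.config.learn_from_delivered
            else record.base_reward
        )
        self.state = utility_update(self.state, record, self._params(record.stake), lr)


def simulate_utility(
    params: UtilityParams,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    group: str = "unknown",
    params_high: UtilityParams | None = None,
    walks=None,
) -> Session:
    """Simulate one subject under the utility model; stores ground truth."""
    agent = UtilityAgent(params, config, params_high=params_high)
    truth = {f"{k}_low": v for k, v in params.as_dict().items()}
    truth.update(
        {f"{k}_high": v for k, v in (params_high or params).as_dict().items()}
    )
    return build_session(
        config, agent, seed,
        subject_id=subject_id, group=group, true_params=truth, walks=walks,
    )
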