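"""Dual-system reinforcement-learning model of the two-step task.

A model-free SARSA(lambda) learner and a model-based planner over the
transition structure each value the two first-stage spaceships; their
values are mixed by a stake-conditional weight omega (omega_low on
low-stake trials, omega_high on high-stake trials) and passed through a
softmax with inverse temperature beta plus choice- and response-stickiness
terms (pi, rho).  Parameters are estimated per subject by maximum a
posteriori optimization under empirical priors — Beta(2,2) on the
unit-interval parameters, Gamma(3, 0.2) on beta, N(0,1) on the stickiness
terms — with many random restarts; an "exhaustive" variant lets every
parameter differ between the stake conditions (12 parameters over a single
shared value table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from ._fastcore import hybrid_loglik
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
    transition,
)

_LOG_2PI = math.log(2.0 * math.pi)


class FittingError(RuntimeError):
    """All optimizer restarts failed to produce a finite posterior."""


# --------------------------------------------------------------------------
# Priors
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Prior:
    """A univariate empirical prior: beta, gamma, normal or flat.

    Gamma is shape-scale by default; ``gamma_rate=True`` switches the second
    hyperparameter to a rate.
    """

    family: str
    p1: float
    p2: float
    gamma_rate: bool = False

    @classmethod
    def beta_prior(cls, a: float, b: float) -> "Prior":
        return cls("beta", a, b)

    @classmethod
    def gamma_prior(cls, shape: float, scale: float, rate: bool = False) -> "Prior":
        return cls("gamma", shape, scale, gamma_rate=rate)

    @classmethod
    def normal_prior(cls, mean: float, sd: float) -> "Prior":
        return cls("normal", mean, sd)

    @classmethod
    def flat_prior(cls, lo: float, hi: float) -> "Prior":
        return cls("flat", lo, hi)

    def _scale(self) -> float:
        return 1.0 / self.p2 if self.gamma_rate else self.p2

    def logpdf(self, x: float) -> float:
        if self.family == "beta":
            if x <= 0.0 or x >= 1.0:
                return -math.inf
            a, b = self.p1, self.p2
            return (
                (a - 1.0) * math.log(x)
                + (b - 1.0) * math.log1p(-x)
                + math.lgamma(a + b)
                - math.lgamma(a)
                - math.lgamma(b)
            )
        if self.family == "gamma":
            if x <= 0.0:
                return -math.inf
            k, th = self.p1, self._scale()
            return (k - 1.0) * math.log(x) - x / th - k * math.log(th) - math.lgamma(k)
        if self.family == "normal":
            z = (x - self.p1) / self.p2
            return -0.5 * z * z - math.log(self.p2) - 0.5 * _LOG_2PI
        if self.family == "flat":
            if x < self.p1 or x > self.p2:
                return -math.inf
            return -math.log(self.p2 - self.p1)
        raise ValueError(f"unknown prior family {self.family!r}")

    def mode(self) -> float:
        if self.family == "beta":
            a, b = self.p1, self.p2
            if a > 1 and b > 1:
                return (a - 1.0) / (a + b - 2.0)
            raise ValueError("beta prior mode undefined for a<=1 or b<=1")
        if self.family == "gamma":
            k, th = self.p1, self._scale()
            if k < 1:
                raise ValueError("gamma prior mode undefined for shape < 1")
            return (k - 1.0) * th
        if self.family == "normal":
            return self.p1
        if self.family == "flat":
            return 0.5 * (self.p1 + self.p2)
        raise ValueError(f"unknown prior family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "beta":
            return float(rng.beta(self.p1, self.p2))
        if self.family == "gamma":
            return float(rng.gamma(self.p1, self._scale()))
        if self.family == "normal":
            return float(rng.normal(self.p1, self.p2))
        if self.family == "flat":
            return float(rng.uniform(self.p1, self.p2))
        raise ValueError(f"unknown prior family {self.family!r}")

    def opt_bounds(self, margin: float = 1e-6) -> tuple[float, float]:
        """Optimizer box, nudged strictly inside the prior support."""
        if self.family == "beta":
            return (margin, 1.0 - margin)
        if self.family == "gamma":
            return (margin, 50.0)
        if self.family == "normal":
            return (self.p1 - 10.0 * self.p2, self.p1 + 10.0 * self.p2)
        if self.family == "flat":
            return (self.p1 + margin, self.p2 - margin)
        raise ValueError(f"unknown prior family {self.family!r}")

    def to_json_obj(self) -> dict:
        if self.family == "beta":
            return {"family": "beta", "a": self.p1, "b": self.p2}
        if self.family == "gamma":
            key = "rate" if self.gamma_rate else "scale"
            return {"family": "gamma", "shape": self.p1, key: self.p2}
        if self.family == "normal":
            return {"family": "normal", "mean": self.p1, "sd": self.p2}
        return {"family": "flat", "lo": self.p1, "hi": self.p2}

    @classmethod
    def from_json_obj(cls, doc: Mapping) -> "Prior":
        fam = doc["family"]
        if fam == "beta":
            return cls.beta_prior(doc["a"], doc["b"])
        if fam == "gamma":
            if "rate" in doc:
                return cls.gamma_prior(doc["shape"], doc["rate"], rate=True)
            return cls.gamma_prior(doc["shape"], doc["scale"])
        if fam == "normal":
            return cls.normal_prior(doc["mean"], doc["sd"])
        if fam == "flat":
            return cls.flat_prior(doc["lo"], doc["hi"])
        raise ValueError(f"unknown prior family {fam!r}")


class PriorSpec:
    """Per-parameter priors, addressable by base name (``alpha_low`` and
    ``alpha_high`` share the ``alpha`` prior)."""

    def __init__(self, priors: Mapping[str, Prior]):
        self.priors = dict(priors)

    def prior_for(self, name: str) -> Prior:
        if name in self.priors:
            return self.priors[name]
        for suffix in ("_low", "_high"):
            if name.endswith(suffix):
                base = name[: -len(suffix)]
                if base in self.priors:
                    return self.priors[base]
        raise KeyError(f"no prior for parameter {name!r}")

    def logpdf(self, name: str, x: float) -> float:
        return self.prior_for(name).logpdf(x)

    def total_logpdf(self, values: Mapping[str, float]) -> float:
        return sum(self.logpdf(n, v) for n, v in values.items())

    def to_json_obj(self) -> dict:
        return {n: p.to_json_obj() for n, p in self.priors.items()}

    @classmethod
    def from_json_obj(cls, doc: Mapping) -> "PriorSpec":
        return cls({n: Prior.from_json_obj(p) for n, p in doc.items()})


def default_priors(gamma_rate: bool = False, rho_beta: bool = False) -> PriorSpec:
    """The empirical priors used for MAP fitting.

    Beta(2,2) on alpha, lambda and the mixing weights; Gamma(3, 0.2) on the
    inverse temperature (shape-scale by default, mode 0.4); N(0,1) on the
    stickiness terms.  ``rho_beta=True`` selects the alternative reading in
    which the response stickiness is also Beta(2,2)-distributed on [0, 1].
    """
    spec = {
        "alpha": Prior.beta_prior(2, 2),
        "lam": Prior.beta_prior(2, 2),
        "w_low": Prior.beta_prior(2, 2),
        "w_high": Prior.beta_prior(2, 2),
        "w": Prior.beta_prior(2, 2),
        "beta": Prior.gamma_prior(3, 0.2, rate=gamma_rate),
        "pi": Prior.normal_prior(0, 1),
        "rho": Prior.beta_prior(2, 2) if rho_beta else Prior.normal_prior(0, 1),
    }
    return PriorSpec(spec)


# --------------------------------------------------------------------------
# Parameters and value state
# --------------------------------------------------------------------------

PARAM_NAMES = ("alpha", "beta", "lam", "w_low", "w_high", "pi", "rho")
EX_PARAM_NAMES = (
    "alpha_low", "alpha_high", "beta_low", "beta_high", "lam_low", "lam_high",
    "w_low", "w_high", "pi_low", "pi_high", "rho_low", "rho_high",
)


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


@dataclass(frozen=True)
class HybridParams:
    """The seven dual-system parameters."""

    alpha: float
    beta: float
    lam: float
    w_low: float
    w_high: float
    pi: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "w_low", "w_high"):
            _check_unit(name, getattr(self, name))
        if not (math.isfinite(self.beta) and self.beta >= 0.0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        if not (math.isfinite(self.pi) and math.isfinite(self.rho)):
            raise ValueError("pi and rho must be finite")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def stake_vectors(self) -> dict[str, np.ndarray]:
        """(low, high) parameter pairs for the likelihood kernel."""
        return {
            "alpha2": np.array([self.alpha, self.alpha]),
            "beta2": np.array([self.beta, self.beta]),
            "lam2": np.array([self.lam, self.lam]),
            "w2": np.array([self.w_low, self.w_high]),
            "pi2": np.array([self.pi, self.pi]),
            "rho2": np.array([self.rho, self.rho]),
        }


@dataclass(frozen=True)
class ExhaustiveParams:
    """Stake-split variant: every parameter has a low- and a high-stake value."""

    alpha_low: float
    alpha_high: float
    beta_low: float
    beta_high: float
    lam_low: float
    lam_high: float
    w_low: float
    w_high: float
    pi_low: float
    pi_high: float
    rho_low: float
    rho_high: float

    def __post_init__(self) -> None:
        for name in ("alpha_low", "alpha_high", "lam_low", "lam_high", "w_low", "w_high"):
            _check_unit(name, getattr(self, name))
        for name in ("beta_low", "beta_high"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @classmethod
    def tied(cls, p: HybridParams) -> "ExhaustiveParams":
        return cls(
            alpha_low=p.alpha, alpha_high=p.alpha,
            beta_low=p.beta, beta_high=p.beta,
            lam_low=p.lam, lam_high=p.lam,
            w_low=p.w_low, w_high=p.w_high,
            pi_low=p.pi, pi_high=p.pi,
            rho_low=p.rho, rho_high=p.rho,
        )

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in EX_PARAM_NAMES}

    def stake_vectors(self) -> dict[str, np.ndarray]:
        return {
            "alpha2": np.array([self.alpha_low, self.alpha_high]),
            "beta2": np.array([self.beta_low, self.beta_high]),
            "lam2": np.array([self.lam_low, self.lam_high]),
            "w2": np.array([self.w_low, self.w_high]),
            "pi2": np.array([self.pi_low, self.pi_high]),
            "rho2": np.array([self.rho_low, self.rho_high]),
        }


def stake_slice(params: HybridParams | ExhaustiveParams, stake: str):
    """The (alpha, beta, lam, w, pi, rho) in force on a trial of this stake."""
    idx = 0 if stake == "low" else 1
    v = params.stake_vectors()
    return tuple(float(v[k][idx]) for k in ("alpha2", "beta2", "lam2", "w2", "pi2", "rho2"))


@dataclass
class ValueState:
    """Model-free Q table and eligibility traces.

    ``q1``/``e1`` index the four first-stage (state, action) pairs;
    ``q2``/``e2`` the two planet states (single forced action each).
    """

    q1: np.ndarray
    q2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    @classmethod
    def zeros(cls) -> "ValueState":
        return cls(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2))

    def copy(self) -> "ValueState":
        return ValueState(self.q1.copy(), self.q2.copy(), self.e1.copy(), self.e2.copy())

    def q(self, key) -> float:
        """Value lookup by (state, action) pair or planet name."""
        if isinstance(key, str):
            return float(self.q2[PLANET_INDEX[key]])
        s, a = key
        return float(self.q1[s - 1, ACTION_INDEX[a]])


@dataclass(frozen=True)
class ChoiceContext:
    """Previous-trial choice identity (the planet the chosen spaceship
    leads to) and physical response key; both None on the first trial."""

    prev_planet_choice: str | None = None
    prev_response_key: str | None = None


# --------------------------------------------------------------------------
# Model operations
# --------------------------------------------------------------------------


def mf_update(
    state: ValueState,
    trial: TrialRecord,
    params: HybridParams | ExhaustiveParams,
    learning_reward: float | None = None,
) -> ValueState:
    """One trial of SARSA(lambda).

    Traces are zeroed at trial start.  Stage 1: the chosen pair's trace is
    incremented, the bootstrap error delta1 = Q(planet) - Q(s1, a1) updates
    all pairs through their traces, then all traces decay by lambda.
    Stage 2: the planet's trace is incremented, the reward error
    delta2 = r - Q(planet) updates all pairs (reaching the first-stage pair
    through its lambda-decayed trace), and traces decay again.
    """
    alpha, _, lam, _, _, _ = stake_slice(params, trial.stake)
    if learning_reward is None:
        learning_reward = trial.base_reward
    q1, q2 = state.q1.copy(), state.q2.copy()
    e1 = np.zeros((2, 2))
    e2 = np.zeros(2)
    s = trial.start_state - 1
    a = ACTION_INDEX[trial.action]
    pl = PLANET_INDEX[trial.planet]

    e1[s, a] += 1.0
    delta1 = q2[pl] - q1[s, a]
    q1 += alpha * delta1 * e1
    q2 += alpha * delta1 * e2
    e1 *= lam
    e2 *= lam

    e2[pl] += 1.0
    delta2 = learning_reward - q2[pl]
    q1 += alpha * delta2 * e1
    q2 += alpha * delta2 * e2
    e1 *= lam
    e2 *= lam
    return ValueState(q1, q2, e1, e2)


def mb_values(state: ValueState, config: TaskConfig) -> np.ndarray:
    """Model-based first-stage values: expected planet value under the
    transition structure, Q_MB(s, a) = sum_p P(p | s, a) Q_MF(p).
    (At the second stage the systems coincide, so Q_MB there is ``state.q2``.)
    """
    P = config.transition_probs()
    return P @ state.q2


def mix_values(q_mb, q_mf, omega: float):
    """Convex mixture Q_net = omega * Q_MB + (1 - omega) * Q_MF."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    return omega * np.asarray(q_mb, dtype=float) + (1.0 - omega) * np.asarray(q_mf, dtype=float)


def choice_probabilities(
    q_net,
    ctx: ChoiceContext,
    trial_layout: Mapping[str, tuple[str, str]],
    params,
) -> np.ndarray:
    """Softmax over the two first-stage actions.

    p(a) is proportional to exp[beta * (Q_net(a) + pi * rep(a) + rho * resp(a))],
    where rep(a)=1 iff a leads to the planet chosen on the previous trial and
    resp(a)=1 iff a's key matches the previous response key.
    ``trial_layout`` maps each action to its (planet, key).
    """
    q = np.asarray(q_net, dtype=float)
    if q.shape != (2,) or not np.all(np.isfinite(q)):
        raise ValueError("q_net must be two finite values")
    beta, pi, rho = float(params.beta), float(params.pi), float(params.rho)
    logits = np.empty(2)
    for j, a in enumerate(ACTIONS):
        planet, key = trial_layout[a]
        rep = 1.0 if planet == ctx.prev_planet_choice else 0.0
        resp = 1.0 if key == ctx.prev_response_key else 0.0
        logits[j] = beta * (q[j] + pi * rep + rho * resp)
    m = logits.max()
    ex = np.exp(logits - m)
    return ex / ex.sum()


def session_log_likelihood(
    params: HybridParams | ExhaustiveParams, session: Session
) -> float:
    """Summed log probability of the observed first-stage choices.

    The second stage has a single forced action and contributes log 1 = 0.
    For ExhaustiveParams, each trial uses the parameter set of its stake
    condition over one shared value table.
    """
    arr = session_arrays(session)
    v = params.stake_vectors()
    cfg = session.config
    return float(
        hybrid_loglik(
            arr["stake"], arr["s1"], arr["a1"], arr["planet"], arr["key_a"],
            arr["reward"],
            v["alpha2"], v["beta2"], v["lam2"], v["w2"], v["pi2"], v["rho2"],
            cfg.transition_probs(), cfg.modal_planets(),
        )
    )


def log_posterior(
    params: HybridParams | ExhaustiveParams,
    session: Session,
    priors: PriorSpec,
) -> float:
    """Log likelihood plus summed log prior densities (-inf off-support)."""
    prior_term = priors.total_logpdf(params.as_dict())
    if not math.isfinite(prior_term):
        return -math.inf
    return session_log_likelihood(params, session) + prior_term


# --------------------------------------------------------------------------
# MAP fitting
# --------------------------------------------------------------------------


def _run_map(
    session: Session,
    priors: PriorSpec,
    names: tuple[str, ...],
    builder,
    model: str,
    n_restarts: int,
    seed: int,
    fixed: Mapping[str, float] | None,
    ties: Mapping[str, str] | None,
) -> FitResult:
    fixed = dict(fixed or {})
    ties = dict(ties or {})
    free = [n for n in names if n not in fixed and n not in ties]
    if not free:
        raise ValueError("no free parameters")
    bounds = [priors.prior_for(n).opt_bounds() for n in free]
    arr = session_arrays(session)
    cfg = session.config
    P = cfg.transition_probs()
    pmod = cfg.modal_planets()

    def full_values(x: np.ndarray) -> dict[str, float]:
        vals = dict(fixed)
        vals.update({n: float(xi) for n, xi in zip(free, x)})
        for tgt, src in ties.items():
            vals[tgt] = vals[src]
        return vals

    def neg_lp(x: np.ndarray) -> float:
        vals = full_values(x)
        prior_term = priors.total_logpdf(vals)
        if not math.isfinite(prior_term):
            return 1e12
        p = builder(vals)
        v = p.stake_vectors()
        ll = hybrid_loglik(
            arr["stake"], arr["s1"], arr["a1"], arr["planet"], arr["key_a"],
            arr["reward"],
            v["alpha2"], v["beta2"], v["lam2"], v["w2"], v["pi2"], v["rho2"],
            P, pmod,
        )
        return -(ll + prior_term)

    rng = np.random.default_rng(seed)
    best = None
    best_idx = -1
    failures: list[str] = []
    for r in range(n_restarts):
        x0 = np.array(
            [
                min(max(priors.prior_for(n).sample(rng), lo), hi)
                for n, (lo, hi) in zip(free, bounds)
            ]
        )
        try:
            res = optimize.minimize(neg_lp, x0, method="L-BFGS-B", bounds=bounds)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"restart {r}: {exc}")
            continue
        if not np.isfinite(res.fun):
            failures.append(f"restart {r}: non-finite objective")
            continue
        if best is None or res.fun < best.fun:
            best = res
            best_idx = r
    if best is None:
        raise FittingError(
            f"all {n_restarts} restarts failed: " + "; ".join(failures[:5])
        )
    estimates = full_values(best.x)
    params = builder(estimates)
    ll = session_log_likelihood(params, session)
    return FitResult(
        model=model,
        estimates=estimates,
        log_likelihood=ll,
        log_posterior=-float(best.fun),
        n_restarts_run=n_restarts,
        best_restart=best_idx,
        converged=bool(best.success),
        seed=seed,
    )


def fit_map(
    session: Session,
    priors: PriorSpec | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
    tie_omega: bool = False,
) -> FitResult:
    """MAP fit of the seven-parameter dual-system model.

    Restart initial points are drawn from the priors; the best restart by
    posterior is returned (ties broken by first occurrence).  ``fixed``
    clamps named parameters; ``tie_omega`` constrains w_high = w_low.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = priors or default_priors()
    ties = {"w_high": "w_low"} if tie_omega else None
    return _run_map(
        session, priors, PARAM_NAMES, lambda v: HybridParams(**v),
        "hybrid", n_restarts, seed, fixed, ties,
    )


def fit_exhaustive(
    session: Session,
    priors: PriorSpec | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    fixed: Mapping[str, float] | None = None,
) -> FitResult:
    """MAP fit of the 12-parameter stake-split model (same priors per base name)."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = priors or default_priors()
    return _run_map(
        session, priors, EX_PARAM_NAMES, lambda v: ExhaustiveParams(**v),
        "exhaustive", n_restarts, seed, fixed, None,
    )


# --------------------------------------------------------------------------
# Generative use
# --------------------------------------------------------------------------


class HybridAgent:
    """Plays the dual-system model generatively through the task."""

    def __init__(self, params: HybridParams, config: TaskConfig):
        self.params = params
        self.config = config
        self.state = ValueState.zeros()
        self.ctx = ChoiceContext()

    def choose(self, obs, rng: np.random.Generator) -> str:
        _, _, _, w, _, _ = stake_slice(self.params, obs.stake)
        s = obs.start_state - 1
        q_mb = mb_values(self.state, self.config)[s]
        q_net = mix_values(q_mb, self.state.q1[s], w)
        probs = choice_probabilities(q_net, self.ctx, obs.layout, self.params)
        return ACTIONS[int(rng.choice(2, p=probs))]

    def observe(self, record: TrialRecord) -> None:
        lr = (
            record.delivered_reward
            if self.config.learn_from_delivered
            else record.base_reward
        )
        self.state = mf_update(self.state, record, self.params, lr)
        self.ctx = ChoiceContext(
            prev_planet_choice=transition(record.start_state, record.action, self.config),
            prev_response_key=record.response_key,
        )


def simulate_hybrid(
    params: HybridParams,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    group: str = "unknown",
) -> Session:
    """Simulate one subject: sample choices from the model's own softmax
    while learning trial-by-trial; the generating parameters are stored on
    the session as ground truth."""
    agent = HybridAgent(params, config)
    return build_session(
        config, agent, seed,
        subject_id=subject_id, group=group, true_params=params.as_dict(),
    )
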