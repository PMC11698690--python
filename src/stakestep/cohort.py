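"""Simulated study cohorts: two groups with group-specific parameter
distributions, a full task session per subject, and ground-truth records.

The shipped presets emulate the study's qualitative group structure:
non-users increase model-based control with the stakes (omega_high >
omega_low), users do not; both groups are more risk averse on high stakes
with a smaller rise in the user group.  Effect sizes are package choices
(the study reports no group parameter means), stored in
``data/presets.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy import stats

from .hybrid import HybridParams, simulate_hybrid
from .task import ConfigError, Session, TaskConfig, validate_session
from .utility import UtilityParams, simulate_utility

GROUP_LABELS = ("nonuser", "user")


@dataclass(frozen=True)
class ParamDist:
    """Truncated-Gaussian marginal for one subject-level parameter."""

    loc: float
    scale: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ConfigError(f"empty truncation interval [{self.low}, {self.high}]")
        if self.scale < 0:
            raise ConfigError("scale must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.scale == 0.0:
            return float(self.loc)
        a = (self.low - self.loc) / self.scale
        b = (self.high - self.loc) / self.scale
        return float(
            stats.truncnorm.rvs(a, b, loc=self.loc, scale=self.scale, random_state=rng)
        )


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    param_dists: Mapping[str, ParamDist]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")


@dataclass
class CohortDataset:
    sessions: list[Session]
    truth: list[dict]
    provenance: dict = field(default_factory=dict)


def load_presets() -> dict:
    """The version-controlled group presets (truncated-normal marginals)."""
    text = resources.files("stakestep").joinpath("data/presets.json").read_text()
    return json.loads(text)


def preset_group_specs(
    agent_kind: str,
    n_nonuser: int = 34,
    n_user: int = 47,
    seed: int = 0,
    overrides: Mapping[str, Mapping[str, ParamDist]] | None = None,
) -> list[GroupSpec]:
    """Study-emulating group specs for ``agent_kind`` ('hybrid' or 'utility').

    Default group sizes follow the study sample (34 non-users, 47 users).
    ``overrides`` replaces named parameter marginals per group label.
    """
    presets = load_presets()
    if agent_kind not in presets:
        raise ConfigError(f"unknown agent kind {agent_kind!r}")
    specs = []
    sizes = {"nonuser": n_nonuser, "user": n_user}
    for gi, label in enumerate(GROUP_LABELS):
        dists = {
            name: ParamDist(**entry) for name, entry in presets[agent_kind][label].items()
        }
        if overrides and label in overrides:
            dists.update(overrides[label])
        specs.append(
            GroupSpec(
                label=label,
                n_subjects=sizes[label],
                param_dists=dists,
                seed=int(np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31)),
            )
        )
    return specs


def draw_subject_params(spec: GroupSpec, subject_index: int) -> dict[str, float]:
    """Independent truncated-Gaussian draws, reproducible from
    (spec.seed, subject_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index]))
    return {name: dist.draw(rng) for name, dist in spec.param_dists.items()}


def _session_seed(spec: GroupSpec, subject_index: int) -> int:
    return int(
        np.random.SeedSequence([spec.seed, subject_index, 1]).generate_state(1)[0]
        % (2**31)
    )


def generate_cohort(
    specs: list[GroupSpec],
    config: TaskConfig | None = None,
    agent_kind: str = "hybrid",
) -> CohortDataset:
    """Draw per-subject parameters and simulate one full session each."""
    if not specs:
        raise ConfigError("at least one group spec is required")
    if agent_kind not in ("hybrid", "utility"):
        raise ConfigError(f"unknown agent kind {agent_kind!r}")
    config = config or TaskConfig()
    sessions: list[Session] = []
    truth: list[dict] = []
    for spec in specs:
        for i in range(spec.n_subjects):
            subject_id = f"{spec.label}_{i:03d}"
            params = draw_subject_params(spec, i)
            seed = _session_seed(spec, i)
            if agent_kind == "hybrid":
                sess = simulate_hybrid(
                    HybridParams(**params), config, seed,
                    subject_id=subject_id, group=spec.label,
                )
            else:
                low = UtilityParams(
                    mu=params["mu_low"], beta_u=params["beta_u"], eta=params["eta"],
                    gamma_disc=params["gamma_disc"], delta_limit=params["delta_limit"],
                )
                high = UtilityParams(
                    mu=params["mu_high"], beta_u=params["beta_u"], eta=params["eta"],
                    gamma_disc=params["gamma_disc"], delta_limit=params["delta_limit"],
                )
                sess = simulate_utility(
                    low, config, seed,
                    subject_id=subject_id, group=spec.label, params_high=high,
                )
            validate_session(sess)
            sessions.append(sess)
            truth.append({"subject_id": subject_id, "group": spec.label, **params})
    provenance = {
        "agent_kind": agent_kind,
        "group_seeds": {s.label: s.seed for s in specs},
        "n_trials": config.n_trials,
    }
    return CohortDataset(sessions=sessions, truth=truth, provenance=provenance)
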