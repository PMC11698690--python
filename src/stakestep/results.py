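"""Common fit-result container shared by the MAP and GA fitters."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FitResult:
    """Point estimates plus provenance of a single-subject model fit.

    ``n_restarts_run`` counts optimizer restarts for MAP fits and
    generations for GA fits; ``best_restart`` is the restart (or
    generation) that produced the returned estimates.
    """

    model: str
    estimates: dict[str, float]
    log_likelihood: float
    log_posterior: float
    n_restarts_run: int
    best_restart: int
    converged: bool
    seed: int
    extra: dict = field(default_factory=dict)
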