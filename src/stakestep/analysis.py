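"""Group-level statistics over per-subject parameter fits.

Covers the study's statistical battery: a 2x2 mixed ANOVA (stakes
within-subject x group between-subject), Mann-Whitney / Wilcoxon rank
tests, Spearman correlations with Bonferroni correction, Fisher z
comparison of two independent correlations, split-half refits, and a
parameter-recovery report for simulated cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .cohort import CohortDataset
from .task import Session


class StatisticalError(ValueError):
    """The data cannot support the requested test (e.g. a missing group)."""


@dataclass(frozen=True)
class EffectStat:
    F: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    stakes: EffectStat
    group: EffectStat
    interaction: EffectStat


@dataclass(frozen=True)
class RankTest:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    rho: float
    n: int
    p_raw: float
    p_adjusted: float
    family_size: int
    undefined: bool = False


@dataclass(frozen=True)
class SplitHalfResult:
    scheme: str
    correlations: pd.DataFrame  # columns: parameter, rho, p, n
    half_estimates: pd.DataFrame


def _columns_for(parameter: str) -> tuple[str, str]:
    mapping = {"omega": ("omega_low", "omega_high"), "mu": ("mu_low", "mu_high")}
    if parameter in mapping:
        return mapping[parameter]
    return (f"{parameter}_low", f"{parameter}_high")


def _check_table(table: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in ("subject_id", "group", *cols) if c not in table.columns]
    if missing:
        raise StatisticalError(f"parameter table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        raise StatisticalError("duplicate subject_ids in parameter table")
    counts = table["group"].value_counts()
    if len(counts) < 2:
        raise StatisticalError("both groups must be present")
    if (counts < 2).any():
        raise StatisticalError("each group needs at least 2 subjects")


def mixed_anova_2x2(table: pd.DataFrame, parameter: str = "omega") -> AnovaResult:
    """Mixed-design ANOVA: stakes (low/high) within-subject, group between.

    With n subjects the interaction is tested on (1, n-2) degrees of
    freedom.  Reports F, p and partial eta squared per effect.
    """
    low_col, high_col = _columns_for(parameter)
    _check_table(table, (low_col, high_col))
    if table[[low_col, high_col]].isna().any().any():
        raise StatisticalError("low and high values required for every subject")
    long = table.melt(
        id_vars=["subject_id", "group"],
        value_vars=[low_col, high_col],
        var_name="stake",
        value_name="value",
    )
    long["stake"] = np.where(long["stake"] == low_col, "low", "high")
    aov = pg.mixed_anova(
        data=long, dv="value", within="stake", subject="subject_id", between="group"
    )
    aov = aov.set_index("Source")

    def eff(source: str) -> EffectStat:
        row = aov.loc[source]
        return EffectStat(
            F=float(row["F"]),
            df1=int(row["DF1"]),
            df2=int(row["DF2"]),
            p_value=float(row["p_unc"]),
            partial_eta_sq=float(row["np2"]),
        )

    return AnovaResult(stakes=eff("stake"), group=eff("group"), interaction=eff("Interaction"))


def rank_tests(table: pd.DataFrame, parameter: str = "omega") -> dict[str, RankTest]:
    """Between-group Mann-Whitney U tests (per stake level and on the
    high-low difference) and within-group Wilcoxon signed-rank tests
    (high vs low); two-sided, normal approximation with continuity and tie
    correction."""
    low_col, high_col = _columns_for(parameter)
    _check_table(table, (low_col, high_col))
    groups = sorted(table["group"].unique())
    g1 = table[table["group"] == groups[0]]
    g2 = table[table["group"] == groups[1]]
    out: dict[str, RankTest] = {}

    def mwu(name: str, x: np.ndarray, y: np.ndarray) -> RankTest:
        if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
            return RankTest(name, math.nan, math.nan, (len(x), len(y)), degenerate=True)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return RankTest(name, float(res.statistic), float(res.pvalue), (len(x), len(y)))

    for label, col in (("low", low_col), ("high", high_col)):
        out[f"mannwhitney_{label}"] = mwu(
            f"mannwhitney_{label}",
            g1[col].to_numpy(float), g2[col].to_numpy(float),
        )
    d1 = (g1[high_col] - g1[low_col]).to_numpy(float)
    d2 = (g2[high_col] - g2[low_col]).to_numpy(float)
    out["mannwhitney_diff"] = mwu("mannwhitney_diff", d1, d2)

    for label, g in ((groups[0], g1), (groups[1], g2)):
        diffs = (g[high_col] - g[low_col]).to_numpy(float)
        name = f"wilcoxon_{label}"
        if np.all(diffs == 0):
            out[name] = RankTest(name, math.nan, math.nan, (len(diffs),), degenerate=True)
            continue
        res = stats.wilcoxon(
            diffs, zero_method="wilcox", correction=True, method="approx",
            alternative="two-sided",
        )
        out[name] = RankTest(name, float(res.statistic), float(res.pvalue), (len(diffs),))
    return out


def spearman_with_bonferroni(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> list[CorrelationResult]:
    """Spearman rank correlation for each requested variable pair, with a
    Bonferroni adjustment over the whole requested family."""
    family = len(pairs)
    out = []
    for x_col, y_col in pairs:
        sub = table[[x_col, y_col]].dropna()
        n = len(sub)
        if n < 4:
            raise StatisticalError(
                f"need >= 4 complete pairs for ({x_col}, {y_col}), got {n}"
            )
        x = sub[x_col].to_numpy(float)
        y = sub[y_col].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out.append(
                CorrelationResult(
                    (x_col, y_col), math.nan, n, math.nan, math.nan, family,
                    undefined=True,
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        out.append(
            CorrelationResult(
                (x_col, y_col), float(rho), n, float(p),
                min(1.0, float(p) * family), family,
            )
        )
    return out


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via the variance-stabilizing
    atanh transform: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),
    with a two-sided normal p-value."""
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise StatisticalError("|r| = 1 makes the Fisher transform infinite")
    if n1 <= 3 or n2 <= 3:
        raise StatisticalError("need more than 3 observations per correlation")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


# --------------------------------------------------------------------------
# Split-half cross-validation and recovery
# --------------------------------------------------------------------------


def split_session(session: Session, scheme: str) -> tuple[Session, Session]:
    """Partition one session's trials into two half-sessions.

    ``first_second`` keeps temporal order (first half gets the extra trial
    when the count is odd); ``odd_even`` separates odd-numbered from
    even-numbered trials (1-based).  Trial indices are renumbered from 0 in
    each half.
    """
    n = len(session.trials)
    if scheme == "first_second":
        cut = (n + 1) // 2
        parts = (session.trials[:cut], session.trials[cut:])
    elif scheme == "odd_even":
        parts = (session.trials[0::2], session.trials[1::2])
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    halves = []
    for tag, trials in zip(("a", "b"), parts):
        renumbered = [dc_replace(tr, trial_index=i) for i, tr in enumerate(trials)]
        halves.append(
            Session(
                subject_id=session.subject_id,
                group=session.group,
                config=session.config.replace(n_trials=len(renumbered)),
                trials=renumbered,
                true_params=session.true_params,
            )
        )
    return halves[0], halves[1]


def split_half_refit(
    sessions: Sequence[Session],
    scheme: str,
    fitter: Callable[[Session], Mapping[str, float]],
    parameters: Sequence[str] | None = None,
) -> SplitHalfResult:
    """Refit each half of every session and correlate half-estimates
    across subjects per parameter (Spearman)."""
    rows = []
    for sess in sessions:
        if len(sess.trials) < 2:
            raise StatisticalError(f"session {sess.subject_id} too short to split")
        half_a, half_b = split_session(sess, scheme)
        est_a = dict(fitter(half_a))
        est_b = dict(fitter(half_b))
        for name in est_a:
            if name in est_b:
                rows.append(
                    {
                        "subject_id": sess.subject_id,
                        "parameter": name,
                        "half_a": est_a[name],
                        "half_b": est_b[name],
                    }
                )
    est = pd.DataFrame(rows)
    params = parameters or sorted(est["parameter"].unique())
    corr_rows = []
    for name in params:
        sub = est[est["parameter"] == name]
        a = sub["half_a"].to_numpy(float)
        b = sub["half_b"].to_numpy(float)
        if len(a) < 4 or np.all(a == a[0]) or np.all(b == b[0]):
            corr_rows.append({"parameter": name, "rho": math.nan, "p": math.nan, "n": len(a)})
            continue
        rho, p = stats.spearmanr(a, b)
        corr_rows.append({"parameter": name, "rho": float(rho), "p": float(p), "n": len(a)})
    return SplitHalfResult(
        scheme=scheme, correlations=pd.DataFrame(corr_rows), half_estimates=est
    )


def parameter_recovery_report(
    cohort: CohortDataset,
    fitter: Callable[[Session], Mapping[str, float]],
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Refit every simulated subject and tabulate, per parameter, the
    Spearman correlation and mean bias between true and recovered values."""
    if not cohort.truth:
        raise ValueError("cohort carries no ground-truth records")
    truth = pd.DataFrame(cohort.truth).set_index("subject_id")
    recovered = {}
    for sess in cohort.sessions:
        if sess.subject_id not in truth.index:
            raise ValueError(f"missing truth record for {sess.subject_id}")
        recovered[sess.subject_id] = dict(fitter(sess))
    rec = pd.DataFrame.from_dict(recovered, orient="index")
    params = parameters or [c for c in rec.columns if c in truth.columns]
    rows = []
    for name in params:
        t = truth.loc[rec.index, name].to_numpy(float)
        r = rec[name].to_numpy(float)
        undefined = bool(np.all(t == t[0]) or np.all(r == r[0]))
        if undefined:
            rho, p = math.nan, math.nan
        else:
            rho, p = stats.spearmanr(t, r)
        rows.append(
            {
                "parameter": name,
                "n": len(t),
                "spearman_rho": float(rho) if not undefined else math.nan,
                "p": float(p) if not undefined else math.nan,
                "bias": float(np.mean(r - t)),
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
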