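"""Independent reference implementations used only by the tests.

Everything here is written as a literal, dictionary-based transcription of
the model equations (explicit eligibility traces over all state-action
pairs, explicit softmax) or as textbook arithmetic (mixed-ANOVA sums of
squares), deliberately sharing no code with the package's likelihood
kernels and fitters.
"""

from __future__ import annotations

import math

FIRST_PAIRS = [(s, a) for s in (1, 2) for a in ("A", "B")]
PLANET_KEYS = [("planet", "red"), ("planet", "purple")]
ALL_PAIRS = FIRST_PAIRS + PLANET_KEYS


def _modal_planet(config, state, action):
    row = config.transition_map[str(state)][action]
    return max(row, key=row.get)


def _logsumexp2(x, y):
    m = max(x, y)
    return m + math.log(math.exp(x - m) + math.exp(y - m))


def handstep_hybrid_loglik(session, params_by_stake):
    """Trial-by-trial stepping of the dual-system model with explicit
    all-pair eligibility traces.

    ``params_by_stake`` maps 'low'/'high' to dicts with keys
    alpha, beta, lam, w, pi, rho (a tied model passes the same dict twice).
    """
    config = session.config
    Q = {pair: 0.0 for pair in ALL_PAIRS}
    prev_planet = None
    prev_key = None
    ll = 0.0
    for tr in session.trials:
        p = params_by_stake[tr.stake]
        s1 = tr.start_state
        # key layout: the chosen action's key is recorded; the other action
        # holds the other key
        other_action = "B" if tr.action == "A" else "A"
        other_key = "right" if tr.response_key == "left" else "left"
        keys = {tr.action: tr.response_key, other_action: other_key}

        logits = {}
        for a in ("A", "B"):
            row = config.transition_map[str(s1)][a]
            qmb = sum(row[pl] * Q[("planet", pl)] for pl in ("red", "purple"))
            qnet = p["w"] * qmb + (1.0 - p["w"]) * Q[(s1, a)]
            rep = 1.0 if _modal_planet(config, s1, a) == prev_planet else 0.0
            resp = 1.0 if keys[a] == prev_key else 0.0
            logits[a] = p["beta"] * (qnet + p["pi"] * rep + p["rho"] * resp)
        ll += logits[tr.action] - _logsumexp2(logits["A"], logits["B"])

        reward = (
            tr.delivered_reward if config.learn_from_delivered else tr.base_reward
        )
        e = {pair: 0.0 for pair in ALL_PAIRS}
        e[(s1, tr.action)] += 1.0
        d1 = Q[("planet", tr.planet)] - Q[(s1, tr.action)]
        for pair in ALL_PAIRS:
            Q[pair] += p["alpha"] * d1 * e[pair]
        for pair in ALL_PAIRS:
            e[pair] *= p["lam"]
        e[("planet", tr.planet)] += 1.0
        d2 = reward - Q[("planet", tr.planet)]
        for pair in ALL_PAIRS:
            Q[pair] += p["alpha"] * d2 * e[pair]
        for pair in ALL_PAIRS:
            e[pair] *= p["lam"]

        prev_planet = _modal_planet(config, s1, tr.action)
        prev_key = tr.response_key
    return ll


def handstep_utility_loglik(session, params, stake_filter="all"):
    """Trial-by-trial stepping of the risk-sensitive utility model."""
    mu = params["mu"]
    beta_u = params["beta_u"]
    eta = params["eta"]
    gam = params["gamma_disc"]
    dlim = params["delta_limit"]
    R = {pair: 0.0 for pair in ALL_PAIRS}
    h = {pair: 0.0 for pair in FIRST_PAIRS}
    ll = 0.0

    def sign(x):
        return (x > 0) - (x < 0)

    def clip(x):
        return max(-dlim, min(dlim, x))

    for tr in session.trials:
        s1 = tr.start_state
        logits = {}
        for a in ("A", "B"):
            u = R[(s1, a)] - mu * sign(R[(s1, a)]) * math.sqrt(h[(s1, a)])
            logits[a] = beta_u * u
        if stake_filter == "all" or tr.stake == stake_filter:
            ll += logits[tr.action] - _logsumexp2(logits["A"], logits["B"])

        reward = (
            tr.delivered_reward if session.config.learn_from_delivered else tr.base_reward
        )
        d1 = clip(gam * R[("planet", tr.planet)] - R[(s1, tr.action)])
        R[(s1, tr.action)] += eta * d1
        d2 = clip(reward - R[("planet", tr.planet)])
        R[("planet", tr.planet)] += eta * d2
        d_eff = d1 + gam * d2
        h[(s1, tr.action)] += eta * (d_eff * d_eff - h[(s1, tr.action)])
    return ll


def mixed_anova_sums_of_squares(data):
    """Textbook mixed-design ANOVA for a balanced 2 (group) x 2 (level)
    layout with one within-subject factor.

    ``data`` maps group label -> list of (low, high) pairs, equal lengths.
    Returns dict with F statistics for group, level and interaction.
    """
    groups = sorted(data)
    k = 2  # within levels
    n_per = {g: len(data[g]) for g in groups}
    N = sum(n_per.values())
    all_vals = [v for g in groups for pair in data[g] for v in pair]
    grand = sum(all_vals) / len(all_vals)

    subj_means = {g: [sum(pair) / k for pair in data[g]] for g in groups}
    group_means = {
        g: sum(v for pair in data[g] for v in pair) / (k * n_per[g]) for g in groups
    }
    level_means = [
        sum(data[g][i][l] for g in groups for i in range(n_per[g])) / N for l in range(k)
    ]
    cell_means = {
        g: [sum(pair[l] for pair in data[g]) / n_per[g] for l in range(k)] for g in groups
    }

    ss_between_subj = k * sum(
        (m - grand) ** 2 for g in groups for m in subj_means[g]
    )
    ss_group = k * sum(n_per[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_subj_within = ss_between_subj - ss_group

    ss_within = sum(
        (data[g][i][l] - subj_means[g][i]) ** 2
        for g in groups
        for i in range(n_per[g])
        for l in range(k)
    )
    ss_level = N * sum((m - grand) ** 2 for m in level_means)
    ss_inter = sum(
        n_per[g]
        * (cell_means[g][l] - group_means[g] - level_means[l] + grand) ** 2
        for g in groups
        for l in range(k)
    )
    ss_err_within = ss_within - ss_level - ss_inter

    df_between_err = N - len(groups)
    df_within_err = (N - len(groups)) * (k - 1)
    return {
        "F_group": (ss_group / (len(groups) - 1)) / (ss_subj_within / df_between_err),
        "F_level": (ss_level / (k - 1)) / (ss_err_within / df_within_err),
        "F_interaction": (ss_inter / (k - 1)) / (ss_err_within / df_within_err),
    }


def spearman_no_ties(x, y):
    """Classic 1 - 6 sum d^2 / (n (n^2 - 1)) for tie-free data."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def mann_whitney_u_brute(x, y):
    """U statistic for x by pair enumeration (ties count half)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u
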