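"""Compiled trial-loop kernels for the session likelihoods.

These mirror, step for step, the public per-trial operations in
``hybrid`` and ``utility``; the test suite checks them against
independently hand-stepped references.  Within a trial only the chosen
first-stage pair and the visited planet carry non-zero eligibility (traces
reset at trial start), so the all-pairs updates reduce to two entries.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def hybrid_loglik(
    stake, s1, a1, planet, key_a, reward,
    alpha2, beta2, lam2, w2, pi2, rho2,
    P, pmod,
):
    """Log-likelihood of the observed first-stage choices under the
    dual-system model.  Parameter arrays hold (low, high) stake values;
    a tied model passes identical pairs.  P is P(planet|state, action),
    pmod the modal planet per pair (defines choice identity for the
    perseveration term)."""
    n = stake.shape[0]
    q1 = np.zeros((2, 2))
    q2 = np.zeros(2)
    ll = 0.0
    prev_pl = -1
    prev_key = -1
    for t in range(n):
        st = stake[t]
        s = s1[t]
        a = a1[t]
        pl = planet[t]
        al = alpha2[st]
        be = beta2[st]
        la = lam2[st]
        w = w2[st]
        pi_ = pi2[st]
        ro = rho2[st]

        x0 = 0.0
        x1 = 0.0
        for j in range(2):
            qmb = P[s, j, 0] * q2[0] + P[s, j, 1] * q2[1]
            qnet = w * qmb + (1.0 - w) * q1[s, j]
            rep = 1.0 if (prev_pl >= 0 and pmod[s, j] == prev_pl) else 0.0
            kj = key_a[t] if j == 0 else 1 - key_a[t]
            resp = 1.0 if (prev_key >= 0 and kj == prev_key) else 0.0
            x = be * (qnet + pi_ * rep + ro * resp)
            if j == 0:
                x0 = x
            else:
                x1 = x
        m = x0 if x0 > x1 else x1
        lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
        ll += (x0 if a == 0 else x1) - lse

        # SARSA(lambda): stage-1 bootstrap update, then stage-2 reward update
        # propagated back through the lambda-decayed trace.
        delta1 = q2[pl] - q1[s, a]
        q1[s, a] += al * delta1
        delta2 = reward[t] - q2[pl]
        q2[pl] += al * delta2
        q1[s, a] += al * delta2 * la

        prev_pl = pmod[s, a]
        prev_key = key_a[t] if a == 0 else 1 - key_a[t]
    return ll


@njit(cache=False)
def utility_loglik(
    s1, a1, planet, reward, include,
    mu, beta_u, eta, gam, dlim,
):
    """Log-likelihood of first-stage choices under the risk-sensitive
    utility model U = R - mu * sign(R) * sqrt(h).  Learning runs over every
    trial; only trials with ``include`` contribute to the sum (stake-
    separated fitting)."""
    n = s1.shape[0]
    r1 = np.zeros((2, 2))
    r2 = np.zeros(2)
    h = np.zeros((2, 2))
    ll = 0.0
    for t in range(n):
        s = s1[t]
        a = a1[t]
        pl = planet[t]

        x0 = 0.0
        x1 = 0.0
        for j in range(2):
            rv = r1[s, j]
            sg = 0.0
            if rv > 0.0:
                sg = 1.0
            elif rv < 0.0:
                sg = -1.0
            u = rv - mu * sg * np.sqrt(h[s, j])
            if j == 0:
                x0 = beta_u * u
            else:
                x1 = beta_u * u
        if include[t] == 1:
            m = x0 if x0 > x1 else x1
            lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m))
            ll += (x0 if a == 0 else x1) - lse

        d1 = gam * r2[pl] - r1[s, a]
        if d1 > dlim:
            d1 = dlim
        elif d1 < -dlim:
            d1 = -dlim
        r1[s, a] += eta * d1
        d2 = reward[t] - r2[pl]
        if d2 > dlim:
            d2 = dlim
        elif d2 < -dlim:
            d2 = -dlim
        r2[pl] += eta * d2
        de = d1 + gam * d2
        h[s, a] += eta * (de * de - h[s, a])
    return ll
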