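"""Dual-system model: updates, values, choice rule, likelihood, MAP fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stakestep.hybrid import (
    ChoiceContext,
    ExhaustiveParams,
    HybridParams,
    Prior,
    ValueState,
    choice_probabilities,
    default_priors,
    fit_exhaustive,
    fit_map,
    log_posterior,
    mb_values,
    mf_update,
    mix_values,
    session_log_likelihood,
    simulate_hybrid,
)
from stakestep.task import TaskConfig, TrialRecord, deliver_reward

from .conftest import make_random_session
from .oracles import handstep_hybrid_loglik


def _params(**kw) -> HybridParams:
    base = dict(alpha=0.5, beta=1.0, lam=0.5, w_low=0.5, w_high=0.5, pi=0.0, rho=0.0)
    base.update(kw)
    return HybridParams(**base)


def _trial(reward=8.0, stake="low", state=1, action="A") -> TrialRecord:
    cfg = TaskConfig()
    return TrialRecord(
        trial_index=0, stake=stake, start_state=state, action=action,
        response_key="left" if action == "A" else "right",
        planet="red" if action == "A" else "purple",
        base_reward=reward, delivered_reward=deliver_reward(reward, stake, cfg),
    )


class TestMfUpdate:
    @pytest.mark.parametrize(
        "lam,expected_q2,expected_q1",
        [
            (0.0, 4.0, 0.0),   # no trace: only the planet value moves
            (1.0, 4.0, 4.0),   # full trace: both pairs move by the same amount
            (0.5, 4.0, 2.0),   # half trace: first-stage pair moves half as far
        ],
    )
    def test_eligibility_propagation(self, lam, expected_q2, expected_q1):
        state = ValueState.zeros()
        out = mf_update(state, _trial(reward=8.0), _params(alpha=0.5, lam=lam))
        assert out.q(("red")) == pytest.approx(expected_q2)
        assert out.q((1, "A")) == pytest.approx(expected_q1)

    def test_zero_learning_rate_leaves_state_unchanged(self):
        state = ValueState.zeros()
        state.q1[:] = 1.5
        out = mf_update(state, _trial(), _params(alpha=0.0))
        np.testing.assert_array_equal(out.q1, state.q1)
        np.testing.assert_array_equal(out.q2, state.q2)

    def test_traces_nonnegative_and_double_decayed(self):
        out = mf_update(ValueState.zeros(), _trial(), _params(lam=0.6))
        # chosen first-stage pair: incremented once, decayed twice
        assert out.e1[0, 0] == pytest.approx(0.6 * 0.6)
        # planet: incremented at stage 2, decayed once
        assert out.e2[0] == pytest.approx(0.6)
        assert np.all(out.e1 >= 0) and np.all(out.e2 >= 0)


class TestValues:
    def test_mb_values_equal_across_start_states(self, default_config):
        state = ValueState.zeros()
        state.q2[:] = [6.0, 2.0]  # red, purple
        q_mb = mb_values(state, default_config)
        # both start states: action A -> red (6), action B -> purple (2)
        np.testing.assert_allclose(q_mb, [[6.0, 2.0], [6.0, 2.0]])

    def test_mb_values_zero(self, default_config):
        np.testing.assert_array_equal(
            mb_values(ValueState.zeros(), default_config), np.zeros((2, 2))
        )

    @pytest.mark.parametrize("omega,expected", [(1.0, 4.0), (0.0, 2.0), (0.5, 3.0)])
    def test_mix_limits_and_midpoint(self, omega, expected):
        assert mix_values(4.0, 2.0, omega) == pytest.approx(expected)

    def test_mix_rejects_bad_omega(self):
        with pytest.raises(ValueError):
            mix_values(1.0, 0.0, 1.5)


LAYOUT = {"A": ("red", "left"), "B": ("purple", "right")}


class TestChoiceProbabilities:
    def test_zero_beta_is_uniform(self):
        p = choice_probabilities([5.0, -3.0], ChoiceContext(), LAYOUT, _params(beta=0.0))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_hand_softmax(self):
        p = choice_probabilities([1.0, 0.0], ChoiceContext(), LAYOUT, _params(beta=1.0))
        np.testing.assert_allclose(p, [0.7311, 0.2689], atol=1e-4)

    def test_perseveration_biases_repeat(self):
        ctx = ChoiceContext(prev_planet_choice="red", prev_response_key=None)
        p = choice_probabilities([0.0, 0.0], ctx, LAYOUT, _params(beta=1.0, pi=0.7))
        assert p[0] > 0.5

    def test_response_stickiness_biases_key(self):
        ctx = ChoiceContext(prev_planet_choice=None, prev_response_key="right")
        p = choice_probabilities([0.0, 0.0], ctx, LAYOUT, _params(beta=1.0, rho=0.7))
        assert p[1] > 0.5

    @given(
        q0=st.floats(-20, 20), q1=st.floats(-20, 20),
        c=st.floats(-50, 50), beta=st.floats(0, 5),
    )
    def test_sums_to_one_and_shift_invariant(self, q0, q1, c, beta):
        params = _params(beta=beta)
        p = choice_probabilities([q0, q1], ChoiceContext(), LAYOUT, params)
        q = choice_probabilities([q0 + c, q1 + c], ChoiceContext(), LAYOUT, params)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p, q, atol=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            choice_probabilities([np.nan, 0.0], ChoiceContext(), LAYOUT, _params())


class TestSessionLikelihood:
    def test_single_trial_uniform(self):
        sess = make_random_session(1, seed=0)
        ll = session_log_likelihood(_params(beta=0.0), sess)
        assert ll == pytest.approx(math.log(0.5))

    def test_empty_session(self):
        sess = make_random_session(0, seed=0)
        assert session_log_likelihood(_params(), sess) == 0.0

    def test_matches_handstep_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(20):
            sess = make_random_session(10, seed=100 + i)
            params = HybridParams(
                alpha=rng.uniform(0.05, 0.95), beta=rng.uniform(0, 2),
                lam=rng.uniform(0, 1), w_low=rng.uniform(0, 1),
                w_high=rng.uniform(0, 1), pi=rng.normal(0, 0.5),
                rho=rng.normal(0, 0.5),
            )
            d = params.as_dict()
            by_stake = {
                "low": {**{k: d[k] for k in ("alpha", "beta", "lam", "pi", "rho")}, "w": d["w_low"]},
                "high": {**{k: d[k] for k in ("alpha", "beta", "lam", "pi", "rho")}, "w": d["w_high"]},
            }
            expected = handstep_hybrid_loglik(sess, by_stake)
            assert session_log_likelihood(params, sess) == pytest.approx(expected, abs=1e-9)

    def test_kernel_matches_stepping_public_operations(self, default_config):
        """The compiled likelihood must equal composing the public per-trial
        operations (softmax at observed state, then mf_update)."""
        sess = make_random_session(30, seed=7)
        params = _params(alpha=0.4, beta=1.3, lam=0.7, w_low=0.2, w_high=0.8, pi=0.3, rho=-0.2)
        from stakestep.hybrid import stake_slice
        from stakestep.task import transition

        state = ValueState.zeros()
        ctx = ChoiceContext()
        total = 0.0
        for tr in sess.trials:
            _, _, _, w, _, _ = stake_slice(params, tr.stake)
            s = tr.start_state - 1
            q_net = mix_values(mb_values(state, sess.config)[s], state.q1[s], w)
            other = "B" if tr.action == "A" else "A"
            other_key = "right" if tr.response_key == "left" else "left"
            layout = {
                tr.action: (transition(tr.start_state, tr.action, sess.config), tr.response_key),
                other: (transition(tr.start_state, other, sess.config), other_key),
            }
            probs = choice_probabilities(q_net, ctx, layout, params)
            total += math.log(probs[0 if tr.action == "A" else 1])
            state = mf_update(state, tr, params)
            ctx = ChoiceContext(
                prev_planet_choice=transition(tr.start_state, tr.action, sess.config),
                prev_response_key=tr.response_key,
            )
        assert session_log_likelihood(params, sess) == pytest.approx(total, abs=1e-9)

    def test_exhaustive_nests_hybrid_exactly(self):
        sess = make_random_session(40, seed=3)
        hp = _params(alpha=0.3, beta=0.9, lam=0.4, w_low=0.2, w_high=0.7, pi=0.1, rho=0.2)
        ep = ExhaustiveParams.tied(hp)
        assert session_log_likelihood(ep, sess) == session_log_likelihood(hp, sess)


class TestPriorsAndPosterior:
    def test_prior_modes(self):
        priors = default_priors()
        assert priors.prior_for("alpha").mode() == pytest.approx(0.5)
        assert priors.prior_for("beta").mode() == pytest.approx(0.4)
        assert priors.prior_for("pi").mode() == 0.0

    def test_logpdfs_match_scipy(self):
        from scipy import stats

        priors = default_priors()
        assert priors.logpdf("alpha", 0.3) == pytest.approx(stats.beta.logpdf(0.3, 2, 2))
        assert priors.logpdf("beta", 0.7) == pytest.approx(
            stats.gamma.logpdf(0.7, 3, scale=0.2)
        )
        assert priors.logpdf("pi", -0.4) == pytest.approx(stats.norm.logpdf(-0.4))

    def test_gamma_rate_reading(self):
        from scipy import stats

        p = Prior.gamma_prior(3, 0.2, rate=True)
        assert p.logpdf(0.7) == pytest.approx(stats.gamma.logpdf(0.7, 3, scale=5.0))
        assert p.mode() == pytest.approx(10.0)

    def test_posterior_on_empty_session_is_prior(self):
        sess = make_random_session(0, seed=0)
        priors = default_priors()
        params = _params()
        assert log_posterior(params, sess, priors) == pytest.approx(
            priors.total_logpdf(params.as_dict())
        )

    def test_boundary_gives_minus_inf(self):
        sess = make_random_session(5, seed=0)
        assert log_posterior(_params(w_low=0.0), sess, default_priors()) == -math.inf

    def test_prior_term_is_parameter_only(self):
        priors = default_priors()
        params = _params(alpha=0.37, beta=0.8)
        diffs = set()
        for seed in (1, 2):
            sess = make_random_session(8, seed=seed)
            diffs.add(
                round(log_posterior(params, sess, priors)
                      - session_log_likelihood(params, sess), 12)
            )
        assert len(diffs) == 1


class TestFitting:
    def test_seeded_determinism(self):
        sess = make_random_session(30, seed=5)
        r1 = fit_map(sess, n_restarts=3, seed=11)
        r2 = fit_map(sess, n_restarts=3, seed=11)
        assert r1.estimates == r2.estimates
        assert r1.log_posterior == r2.log_posterior

    def test_fit_result_posterior_identity(self):
        sess = make_random_session(25, seed=6)
        priors = default_priors()
        res = fit_map(sess, priors, n_restarts=3, seed=1)
        expected = res.log_likelihood + priors.total_logpdf(res.estimates)
        assert res.log_posterior == pytest.approx(expected, abs=1e-6)

    def test_exhaustive_low_only_session_returns_prior_modes_for_high(self):
        sess = make_random_session(25, seed=8)
        # force all trials low-stake
        from dataclasses import replace

        sess.trials = [
            replace(tr, stake="low", delivered_reward=tr.base_reward)
            for tr in sess.trials
        ]
        res = fit_exhaustive(sess, n_restarts=4, seed=2)
        for name, mode in (
            ("alpha_high", 0.5), ("lam_high", 0.5), ("w_high", 0.5),
            ("beta_high", 0.4), ("pi_high", 0.0), ("rho_high", 0.0),
        ):
            assert res.estimates[name] == pytest.approx(mode, abs=1e-3)

    def test_exhaustive_seeded_determinism(self):
        sess = make_random_session(20, seed=9)
        r1 = fit_exhaustive(sess, n_restarts=2, seed=4)
        r2 = fit_exhaustive(sess, n_restarts=2, seed=4)
        assert r1.estimates == r2.estimates

    def test_rejects_zero_restarts(self):
        sess = make_random_session(5, seed=0)
        with pytest.raises(ValueError):
            fit_map(sess, n_restarts=0)


class TestSimulation:
    def test_default_length(self, default_config):
        sess = simulate_hybrid(_params(), default_config, seed=1)
        assert len(sess) == 200
        assert sess.true_params["alpha"] == 0.5

    def test_seeded_determinism(self, default_config):
        a = simulate_hybrid(_params(), default_config, seed=2)
        b = simulate_hybrid(_params(), default_config, seed=2)
        assert a.trials == b.trials

    def test_model_based_agents_outperform_model_free(self, default_config):
        """With equivalent start states and deterministic transitions,
        planning transfers reward information across states, so omega = 1
        agents should collect more base reward than omega = 0 agents."""
        def mean_reward(w):
            totals = []
            for seed in range(40):
                p = _params(alpha=0.7, beta=3.0, lam=0.5, w_low=w, w_high=w)
                sess = simulate_hybrid(p, default_config, seed=seed)
                totals.append(np.mean([t.base_reward for t in sess.trials]))
            return np.mean(totals)

        assert mean_reward(1.0) > mean_reward(0.0)
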