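"""Pavlovian-bias RL model: choice rule, learning rule, likelihood, fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from affectbias.datatypes import SubjectSessionData
from affectbias.gonogo_model import (
    GNGLatentState, GNGParams, compare_models, expand_to_full,
    fit_hierarchical_gng, p_go, pack_gng_sessions, session_loglik,
    trialwise_choice_probs, update_state,
)
from affectbias.hierarchical import McmcConfig
from affectbias.synthetic_cohort import (
    CohortConfig, simulate_cohort, simulate_gng_agent,
)
from affectbias.task_designs import generate_gonogo_schedule


class TestChoiceRule:
    def test_fresh_state_is_indifferent(self):
        p = p_go(GNGLatentState(), GNGParams(epsilon=0.1), "go_to_win")
        assert p == 0.5

    def test_full_lapse_pins_chance(self):
        state = GNGLatentState()
        state.Q[1, 0] = 5.0
        assert p_go(state, GNGParams(epsilon=0.1, xi=1.0), "go_to_win") == 0.5

    def test_go_bias_passes_through_logistic(self):
        p = p_go(GNGLatentState(), GNGParams(epsilon=0.1, b=0.7, xi=0.0),
                 "go_to_win")
        assert p == pytest.approx(expit(0.7), abs=1e-12)

    def test_pavlovian_bias_uses_cue_valence(self):
        state = GNGLatentState()
        state.V[:] = 1.0
        params = GNGParams(epsilon=0.1, pi_approach=2.0, pi_avoid=-1.0)
        assert p_go(state, params, "nogo_to_win") == pytest.approx(expit(2.0))
        assert p_go(state, params, "go_to_avoid") == pytest.approx(expit(-1.0))

    @given(xi=st.floats(0.0, 1.0), q=st.floats(-20, 20), v=st.floats(-20, 20),
           b=st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_lapse_bounds_hold_for_any_state(self, xi, q, v, b):
        state = GNGLatentState()
        state.Q[1, 0] = q
        state.V[0] = v
        params = GNGParams(epsilon=0.5, b=b, pi_approach=1.0, xi=xi)
        p = p_go(state, params, "go_to_win")
        assert xi / 2 - 1e-12 <= p <= 1 - xi / 2 + 1e-12


class TestLearningRule:
    def test_zero_learning_rate_freezes_state(self):
        state = GNGLatentState()
        new = update_state(state, GNGParams(epsilon=0.0), "go_to_win", "go", 10)
        assert np.allclose(new.Q, 0) and np.allclose(new.V, 0)

    def test_single_step_hand_computation(self):
        params = GNGParams(epsilon=0.2, rho_rew=2.0)
        new = update_state(GNGLatentState(), params, "go_to_win", "go", 10)
        assert new.Q[1, 0] == pytest.approx(0.4)
        assert new.V[0] == pytest.approx(0.4)
        assert new.Q[0, 0] == 0.0  # untaken action untouched

    def test_punishment_scales_with_its_own_sensitivity(self):
        params = GNGParams(epsilon=0.5, rho_rew=2.0, rho_pun=3.0)
        new = update_state(GNGLatentState(), params, "go_to_avoid", "go", -10)
        assert new.Q[1, 2] == pytest.approx(-1.5)

    def test_neutral_outcome_updates_toward_zero(self):
        params = GNGParams(epsilon=0.5, rho_rew=2.0)
        state = update_state(GNGLatentState(), params, "go_to_win", "go", 10)
        state = update_state(state, params, "go_to_win", "go", 0)
        assert state.Q[1, 0] == pytest.approx(0.5)

    def test_repeated_reward_converges_to_sensitivity(self):
        params = GNGParams(epsilon=0.3, rho_rew=2.5)
        state = GNGLatentState()
        prev = 0.0
        for _ in range(60):
            state = update_state(state, params, "go_to_win", "go", 10)
            assert state.Q[1, 0] >= prev
            prev = state.Q[1, 0]
        assert state.Q[1, 0] == pytest.approx(2.5, abs=1e-6)


def _toy_session(records):
    return SubjectSessionData("t", 1, "gonogo", pd.DataFrame(
        [(i, c, a, np.nan, o) for i, (c, a, o) in enumerate(records)],
        columns=["trial", "condition", "choice", "rt", "outcome"]))


class TestSessionLoglik:
    def test_full_lapse_gives_uniform_likelihood(self):
        sess = _toy_session([("go_to_win", "go", 10)] * 12)
        ll = session_loglik(GNGParams(epsilon=0.2, xi=1.0), sess)
        assert ll == pytest.approx(12 * np.log(0.5))

    def test_matches_independent_recursion_on_toy(self):
        # independent oracle: explicit Q/V recursion written from scratch
        params = GNGParams(epsilon=0.25, b=0.4, pi_approach=0.6, pi_avoid=0.3,
                           rho_rew=1.8, rho_pun=2.2, xi=0.06)
        records = [("go_to_win", "go", 10), ("go_to_win", "nogo", 0),
                   ("nogo_to_avoid", "go", -10), ("go_to_win", "go", 0),
                   ("nogo_to_avoid", "nogo", 0)]
        q = {("go", c): 0.0 for c, _, _ in records}
        q.update({("nogo", c): 0.0 for c, _, _ in records})
        v = {c: 0.0 for c, _, _ in records}
        expected = 0.0
        for cue, act, out in records:
            pi = params.pi_approach if "win" in cue else params.pi_avoid
            w = q[("go", cue)] + params.b + pi * v[cue] - q[("nogo", cue)]
            pgo = params.xi / 2 + (1 - params.xi) / (1 + np.exp(-w))
            expected += np.log(pgo if act == "go" else 1 - pgo)
            r = out // 10
            u = params.rho_rew * r if r > 0 else params.rho_pun * r
            q[(act, cue)] += params.epsilon * (u - q[(act, cue)])
            v[cue] += params.epsilon * (u - v[cue])
        assert session_loglik(params, _toy_session(records)) == \
            pytest.approx(expected, abs=1e-12)

    def test_trial_order_matters(self):
        params = GNGParams(epsilon=0.3, rho_rew=2.0, rho_pun=2.0, xi=0.0)
        records = [("go_to_win", "go", 10), ("go_to_win", "nogo", 0),
                   ("go_to_win", "go", 0), ("go_to_win", "go", 10)]
        ll = session_loglik(params, _toy_session(records))
        ll_rev = session_loglik(params, _toy_session(records[::-1]))
        assert ll != pytest.approx(ll_rev)

    def test_invalid_choice_code_rejected(self):
        with pytest.raises(ValueError, match="choice"):
            session_loglik(GNGParams(epsilon=0.1),
                           _toy_session([("go_to_win", "press", 10)]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorised_kernel_matches_reference_loop(self, seed):
        rng = np.random.default_rng(seed)
        params = GNGParams(
            epsilon=rng.uniform(0.05, 0.6), b=rng.normal(0, 1),
            pi_approach=rng.normal(0, 1), pi_avoid=rng.normal(0, 1),
            rho_rew=rng.uniform(0.5, 4), rho_pun=rng.uniform(0.5, 4),
            xi=rng.uniform(0.01, 0.3))
        data = simulate_gng_agent(params, generate_gonogo_schedule(seed),
                                  seed=seed + 100)
        _, cues, choices, rewards = pack_gng_sessions([data])
        kernel_ll = float(np.log(trialwise_choice_probs(
            params.as_array()[None, :], cues, choices, rewards)).sum())
        assert kernel_ll == pytest.approx(session_loglik(params, data),
                                          rel=1e-12)


class TestModelFamily:
    def test_reduced_models_share_tied_parameters(self):
        free = np.array([[0.2, 1.5, 0.3, 0.7, 0.05]])  # rw_go_pav order
        full = expand_to_full("rw_go_pav", free)
        eps, b, pa, pv, rr, rp, xi = full[0]
        assert (rr, rp) == (1.5, 1.5)
        assert (pa, pv) == (0.7, 0.7)
        assert (eps, b, xi) == (0.2, 0.3, 0.05)

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            fit_hierarchical_gng([], model_id="nope")


class TestHierarchicalFit:
    def test_group_mean_covers_shared_truth(self):
        # every subject shares one parameter set; the group posterior mean
        # should land close to it
        truth = GNGParams(epsilon=0.25, b=0.4, pi_approach=0.5, pi_avoid=0.5,
                          rho_rew=2.0, rho_pun=2.0, xi=0.05)
        sessions = []
        for i in range(25):
            d = simulate_gng_agent(truth, generate_gonogo_schedule(100 + i),
                                   seed=i)
            d.subject_id = i
            sessions.append(d)
        fit = fit_hierarchical_gng(sessions, mcmc=McmcConfig(
            chains=2, warmup=400, draws=400, seed=9, thin_theta=2))
        got = fit.subject_means[["epsilon", "b", "rho_rew"]].mean()
        assert abs(got["epsilon"] - truth.epsilon) < 0.1
        assert abs(got["b"] - truth.b) < 0.3
        assert abs(got["rho_rew"] - truth.rho_rew) < 0.8

    def test_recovery_quality_reported_in_acceptance(self, gng_fits,
                                                     gng_cohort):
        # detailed gates live in the acceptance suite; here: sane outputs
        fit = gng_fits[1]
        assert set(fit.subject_means.columns) >= {"epsilon", "b", "xi"}
        assert len(fit.subject_means) == 58
        assert (fit.subject_means["epsilon"].between(0, 1)).all()
        assert fit.diagnostics["max_rhat"] < 1.3

    def test_richer_model_shrinks_absent_pavlovian_terms(self):
        # data from a go-bias-only model: fitted Pavlovian biases ~ 0
        truth = GNGParams(epsilon=0.25, b=0.6, rho_rew=2.0, rho_pun=2.0,
                          xi=0.05)
        sessions = []
        for i in range(25):
            d = simulate_gng_agent(truth, generate_gonogo_schedule(200 + i),
                                   seed=1000 + i)
            d.subject_id = i
            sessions.append(d)
        fit = fit_hierarchical_gng(sessions, model_id="rw_go_pav_split",
                                   mcmc=McmcConfig(chains=2, warmup=400,
                                                   draws=400, seed=10,
                                                   thin_theta=2))
        assert abs(fit.subject_means["pi_approach"].mean()) < 0.35
        assert abs(fit.subject_means["pi_avoid"].mean()) < 0.35


class TestModelComparison:
    @pytest.fixture(scope="class")
    def family_fits(self):
        cohort = simulate_cohort(CohortConfig(task="gonogo", n_subjects=40,
                                              seed=41))
        s1 = cohort.sessions(task="gonogo", session=1)
        mc = McmcConfig(chains=2, warmup=400, draws=400, seed=2, thin_theta=2)
        return [fit_hierarchical_gng(s1, model_id=m, mcmc=mc)
                for m in ("rw", "rw_go", "rw_go_pav_split")]

    def test_generating_model_ranks_first(self, family_fits):
        table = compare_models(family_fits)
        assert table.loc[0, "model_id"] == "rw_go_pav_split"
        assert list(table["rank"]) == [1, 2, 3]

    def test_duplicate_fit_ties(self, family_fits):
        table = compare_models([family_fits[0], family_fits[0]])
        assert table["criterion"].iloc[0] == table["criterion"].iloc[1]

    def test_mismatched_data_rejected(self, family_fits, gng_fits):
        with pytest.raises(ValueError, match="identical data"):
            compare_models([family_fits[0], gng_fits[1]])
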