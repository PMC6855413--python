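"""Hybrid agent: transforms, values, choice rules, updates, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.hybrid import (AgentParams, QState, VARIANTS, compute_qmb,
                            inverse_transform_params, session_loglik,
                            stage1_choice_probs, stage2_choice_probs,
                            td_update, transform_params)
from twostep.task import SessionData


def make_session(c1, s2, c2, r, missed=None):
    n = len(c1)
    return SessionData(
        subject_id=0, session=1,
        choice1=np.array(c1, dtype=np.int8), state2=np.array(s2, dtype=np.int8),
        choice2=np.array(c2, dtype=np.int8), reward=np.array(r, dtype=np.int8),
        missed=np.array(missed if missed is not None else [False] * n),
        rt1=np.full(n, 0.5), rt2=np.full(n, 0.5))


class TestTransforms:
    def test_zero_maps_to_unit_betas_and_half_rates(self):
        p = transform_params(np.zeros(7))
        assert p.beta2 == pytest.approx(1.0)
        assert p.bmb == pytest.approx(1.0)
        assert p.alpha1 == pytest.approx(0.5)
        assert p.lam == pytest.approx(0.5)
        assert p.p == 0.0

    def test_round_trip_closed_form(self):
        u = np.array([1.7, -0.3, 0.2, 0.9, -1.1, 0.0, 0.4])
        nat = transform_params(u)
        back = inverse_transform_params(nat)
        np.testing.assert_allclose(back, u, atol=1e-10)

    @given(st.lists(st.floats(-4, 4), min_size=7, max_size=7))
    @settings(deadline=None)
    def test_round_trip_property_all_variants(self, u):
        u = np.asarray(u)
        for name in ("ll2bmfbmb2alr", "llm2b2alr"):
            v = VARIANTS[name]
            nat = v.to_natural(u[: v.n_params])
            # natural-scale bounds hold
            assert nat[0] >= 0 and nat[1] >= 0 and nat[2] >= 0
            assert np.all((nat[3:6] >= 0) & (nat[3:6] <= 1))

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            transform_params([np.nan] * 7)


class TestValues:
    def test_qmb_zero_values(self):
        np.testing.assert_array_equal(compute_qmb(np.zeros((2, 2))), [0, 0])

    def test_qmb_expectation(self):
        q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        qmb = compute_qmb(q2, p_common=0.7)
        assert qmb[0] == pytest.approx(0.7)
        assert qmb[1] == pytest.approx(0.3)

    def test_qmb_symmetric_states(self):
        q2 = np.array([[0.3, 0.6], [0.6, 0.3]])
        qmb = compute_qmb(q2)
        assert qmb[0] == pytest.approx(qmb[1])


class TestChoiceRules:
    def test_symmetric_values_give_uniform(self):
        q = QState.zeros()
        probs = stage1_choice_probs(q, np.array([1, 1, 1, 0.5, 0.5, 0.5, 0.0]))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_stage1_softmax_closed_form(self):
        q = QState.zeros()
        q.q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        # bMB=1, bMF=0, p_common=1 -> logits (1, 0)
        probs = stage1_choice_probs(q, np.array([1, 0, 1, .5, .5, .5, 0.0]),
                                    p_common=1.0)
        assert probs[0] == pytest.approx(math.e / (math.e + 1), abs=1e-12)

    def test_perseveration_closed_form(self):
        q = QState.zeros()
        q.prev_choice1 = 0
        probs = stage1_choice_probs(q, np.array([0, 0, 1, .5, .5, .5, 2.0]))
        assert probs[0] == pytest.approx(math.exp(2) / (math.exp(2) + 1), abs=1e-12)

    def test_first_trial_has_no_perseveration(self):
        q = QState.zeros()  # prev_choice1 == -1
        probs = stage1_choice_probs(q, np.array([0, 0, 1, .5, .5, .5, 5.0]))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_stage2_softmax(self):
        q2 = np.array([[0.5, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(stage2_choice_probs(q2, 0, beta2=0.0), [0.5, 0.5])
        probs = stage2_choice_probs(q2, 0, beta2=2.0)
        assert probs[0] == pytest.approx(math.e / (math.e + 1), abs=1e-12)
        probs = stage2_choice_probs(q2, 0, beta2=500.0)
        assert probs[0] == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.floats(-2, 2), min_size=4, max_size=4),
           st.floats(0, 10))
    @settings(deadline=None)
    def test_stage2_probs_sum_to_one_and_positive(self, q2flat, beta2):
        q2 = np.array(q2flat).reshape(2, 2)
        probs = stage2_choice_probs(q2, 1, beta2)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs > 0)


class TestTdUpdate:
    def trial(self, **kw):
        base = dict(choice1=0, state2=0, choice2=1, reward=1, missed=False)
        base.update(kw)
        return type("T", (), base)()

    def test_zero_learning_rates_freeze_values(self):
        q = QState.zeros()
        td_update(q, self.trial(), np.array([1, 1, 1, 0.0, 0.0, 0.5, 0.0]))
        assert np.all(q.q1_mf == 0) and np.all(q.q2 == 0)
        assert q.prev_choice1 == 0

    def test_two_step_update_hand_trace(self):
        # alpha1=alpha2=0.5, lam=1: stage-2 value 0.5, stage-1 value 0.5
        q = QState.zeros()
        td_update(q, self.trial(), np.array([1, 1, 1, 0.5, 0.5, 1.0, 0.0]))
        assert q.q2[0, 1] == pytest.approx(0.5)
        assert q.q1_mf[0] == pytest.approx(0.5)

    def test_lambda_zero_blocks_reward_backup(self):
        q = QState.zeros()
        td_update(q, self.trial(), np.array([1, 1, 1, 0.5, 0.5, 0.0, 0.0]))
        assert q.q2[0, 1] == pytest.approx(0.5)
        assert q.q1_mf[0] == pytest.approx(0.0)  # delta1 was 0 pre-update

    def test_missed_trial_rejected(self):
        with pytest.raises(ValueError, match="missed"):
            td_update(QState.zeros(), self.trial(missed=True),
                      np.array([1, 1, 1, .5, .5, .5, 0]))


class TestSessionLoglik:
    def test_uniform_choice_likelihood(self):
        sess = make_session([0, 1, 0, 1], [0, 1, 1, 0], [1, 0, 1, 0], [1, 0, 0, 1])
        # betas 0 and p 0 -> both stages uniform
        u = np.array([-30.0, -30.0, -30.0, 0.0, 0.0, 0.0, 0.0])
        ll = session_loglik(u, sess)
        assert ll == pytest.approx(-2 * 4 * math.log(2), abs=1e-6)

    def test_hand_traced_two_trial_session(self):
        """Step-by-step arithmetic oracle for the likelihood recursion."""
        sess = make_session([0, 1], [0, 0], [1, 0], [1, 0])
        ll = session_loglik(np.zeros(7), sess)  # all params at transform(0)
        # trial 0: all values zero -> P(c1)=0.5, P(c2)=0.5
        expected = math.log(0.25)
        # updates: d1 = 0; q2[0,1] = 0.5; q1[0] += 0.5*0.5*1 = 0.25
        # trial 1: Q_MB = (0.7*0.5, 0.3*0.5); logits x0 = 0.35+0.25, x1 = 0.15
        x0, x1 = 0.6, 0.15
        expected += x1 - math.log(math.exp(x0) + math.exp(x1))
        # stage 2 in state 0: values (0, 0.5), chose action 0
        expected += 0.0 - math.log(1.0 + math.exp(0.5))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_missed_trial_contributes_nothing(self):
        sess = make_session([0, 1], [0, 0], [1, 0], [1, 0])
        with_miss = make_session([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1],
                                 missed=[False, False, True])
        u = np.array([0.3, -0.2, 0.5, 0.1, -0.1, 0.2, 0.1])
        assert session_loglik(u, sess) == pytest.approx(
            session_loglik(u, with_miss), abs=1e-12)

    def test_relabeling_symmetry(self, one_session):
        """Simultaneously flipping stage-1 actions, stage-2 states and
        stage-2 actions leaves the likelihood invariant."""
        s = one_session
        flipped = make_session(1 - s.choice1, 1 - s.state2, 1 - s.choice2,
                               s.reward, list(s.missed))
        u = np.array([0.5, 0.2, 0.8, 0.0, -0.3, 0.1, 0.25])
        assert session_loglik(u, s) == pytest.approx(
            session_loglik(u, flipped), abs=1e-9)

    def test_omega_variant_equals_two_beta_reparameterisation(self, one_session):
        """beta1 = b, omega = w is the same model as bMB = b*w, bMF = b*(1-w)."""
        from scipy.special import logit

        b, w = 2.4, 0.3
        rest = [0.7, 0.1, -0.2, 0.3, 0.2]
        u_omega = np.array([math.log(b), logit(w)] + rest)
        u_two = np.array([math.log(b * w), math.log(b * (1 - w))] + rest)
        assert session_loglik(u_omega, one_session, "llm2b2alr") == pytest.approx(
            session_loglik(u_two, one_session, "ll2bmfbmb2alr"), abs=1e-9)

    def test_loglik_nonpositive_and_deterministic(self, one_session):
        u = np.array([0.1, 0.1, 0.4, 0.2, 0.2, 0.0, 0.0])
        a = session_loglik(u, one_session)
        assert a <= 0
        assert a == session_loglik(u, one_session)

    def test_nan_parameters_rejected(self, one_session):
        with pytest.raises(ValueError):
            session_loglik(np.array([np.nan, 0, 0, 0, 0, 0, 0]), one_session)


class TestVariantRegistry:
    def test_anchor_variants_present_with_seven_params(self):
        assert VARIANTS["ll2bmfbmb2alr"].n_params == 7
        assert VARIANTS["llm2b2alr"].n_params == 7
        assert len(VARIANTS) == 8

    def test_parameter_counts_match_flags(self):
        for v in VARIANTS.values():
            expected = 3 + (2 if v.separate_alphas else 1) \
                + v.has_lambda + v.has_perseveration
            assert v.n_params == expected == len(v.param_names)

    def test_agent_params_validation(self):
        with pytest.raises(ValueError):
            AgentParams(bmb=-1, bmf=0, beta2=1, alpha1=.5, alpha2=.5, lam=.5, p=0)
        with pytest.raises(ValueError):
            AgentParams(bmb=1, bmf=0, beta2=1, alpha1=1.5, alpha2=.5, lam=.5, p=0)
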