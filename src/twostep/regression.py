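"""Stay/switch design construction and mixed-effects regression.

The one-trial-back analysis of the two-step task regresses the decision
to repeat the previous stage-1 choice (stay = 1, switch = 0) on the
previous trial's reward (rewarded +1 / unrewarded -1), transition
(common +1 / uncommon -1) and their interaction: a main effect of
reward indexes model-free control, the reward x transition interaction
indexes model-based control. Session enters as a categorical factor
against the reference first session; an optional "correct" predictor
codes whether the previous choice was the objectively better stage-1
action, to keep value differences at trial start from loading on the
interaction term.

The logistic model with per-subject random slopes is fitted by
``lme4::glmer`` through :mod:`twostep._lme4`; the linear variant for
continuous per-trial responses uses ``statsmodels`` MixedLM (REML).
Both report Wald per-term F statistics computed from the fixed-effects
covariance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import _lme4
from .task import SessionData

logger = logging.getLogger(__name__)

__all__ = [
    "StayDesignError", "MixedFitResult", "build_stay_design",
    "MixedLogisticStay", "MixedLinearResponse",
    "fit_mixed_logistic", "fit_mixed_linear",
    "stay_probability_summary", "coefficient_correlation",
    "logistic_null_calibration",
]


class StayDesignError(ValueError):
    pass


@dataclass
class MixedFitResult:
    """Uniform reporting surface for the mixed-effects fits."""

    coefficients: pd.DataFrame   # index: coefficient; estimate, se, z, p, term
    anova: pd.DataFrame          # per-term Wald F table
    re_variance: dict
    converged: bool
    singular: bool
    n_rows: int
    formula: str
    random_formula: str
    backend: str
    messages: list = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients.loc[name, "estimate"])

    def zval(self, name: str) -> float:
        return float(self.coefficients.loc[name, "z"])


def _correct_sign_from_walk(walk_probs: np.ndarray, t: np.ndarray,
                            choice_prev: np.ndarray) -> np.ndarray:
    """+1 where the previous choice led (commonly) to the currently better
    stage-2 state under the true generative walks."""
    v = walk_probs[t - 1].max(axis=2)          # (n, 2) state values
    best = (v[:, 1] > v[:, 0]).astype(int)     # identity common mapping
    return np.where(choice_prev == best, 1, -1)


def _correct_sign_empirical(sess: SessionData, decay: float = 0.9) -> np.ndarray:
    """Fallback 'correct' coding from a decaying running mean of observed
    rewards per stage-2 option (for data without generative walks)."""
    est = np.full((2, 2), 0.5)
    out = np.zeros(len(sess), dtype=int)
    for t in range(len(sess)):
        if not sess.missed[t]:
            v0, v1 = est[0].max(), est[1].max()
            best = int(v1 > v0)
            out[t] = 1 if sess.choice1[t] == best else -1
            s, b = sess.state2[t], sess.choice2[t]
            est[s, b] += (1.0 - decay) * (sess.reward[t] - est[s, b])
    return out


def build_stay_design(cohort, use_walks: bool = True) -> pd.DataFrame:
    """Per-trial stay/switch regression rows for a cohort of sessions.

    A row exists for every trial with a valid predecessor in the same
    session (the first valid trial and trials adjacent to missed trials
    are dropped). Codings: ``stay`` in {0, 1}; ``reward``,
    ``transition`` and ``correct`` in {+1, -1}, all referring to the
    previous trial.
    """
    cols = {k: [] for k in ("subject", "session", "stay", "reward",
                            "transition", "correct")}
    for sess in cohort:
        n = len(sess)
        if n < 2:
            continue
        t = np.arange(1, n)
        ok = sess.valid[t] & sess.valid[t - 1]
        t = t[ok]
        if t.size == 0:
            continue
        cols["subject"].append(np.full(t.size, sess.subject_id))
        cols["session"].append(np.full(t.size, sess.session))
        cols["stay"].append((sess.choice1[t] == sess.choice1[t - 1]).astype(int))
        cols["reward"].append(2 * sess.reward[t - 1].astype(int) - 1)
        common_prev = (sess.state2[t - 1] == sess.choice1[t - 1])
        cols["transition"].append(np.where(common_prev, 1, -1))
        if use_walks and sess.walk is not None:
            corr = _correct_sign_from_walk(sess.walk.probs, t, sess.choice1[t - 1])
        else:
            corr = _correct_sign_empirical(sess)[t - 1]
        cols["correct"].append(corr)
    if not cols["stay"]:
        raise StayDesignError("no analyzable consecutive trial pairs in cohort")
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


_SESSION_LEVEL = re.compile(r"(session)(\d+)|(C\(session\)\[T\.)(\d+)(\])")


def _term_of(coef_name: str) -> str:
    """Map a coefficient name to its model term (factor levels collapsed)."""
    name = re.sub(r"C\(session\)\[T\.\d+\]", "session", coef_name)
    name = re.sub(r"session\d+", "session", name)
    return "Intercept" if "Intercept" in name else name


def _wald_table(coef: pd.DataFrame, vcov: np.ndarray, n_rows: int) -> pd.DataFrame:
    """Per-term Wald F statistics from the fixed-effect covariance."""
    terms = coef["term"].unique()
    p_total = len(coef)
    rows = []
    for term in terms:
        idx = np.flatnonzero((coef["term"] == term).to_numpy())
        b = coef["estimate"].to_numpy()[idx]
        v = vcov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            chi2 = np.nan
        q = len(idx)
        df2 = max(n_rows - p_total, 1)
        f = chi2 / q
        rows.append({"term": term, "F": f, "df1": q, "df2": df2,
                     "p": stats.f.sf(f, q, df2) if np.isfinite(f) else np.nan})
    return pd.DataFrame(rows)


def _scalar(x):
    return np.asarray(x).ravel()[0]


def _result_from_lme4(out: dict, fixed: str, backend: str) -> MixedFitResult:
    names = list(out["coef_names"])
    est = np.asarray(out["estimate"], dtype=float)
    vcov = np.asarray(out["vcov"], dtype=float).reshape(len(names), len(names))
    se = np.sqrt(np.diag(vcov))
    z = est / se
    coef = pd.DataFrame({
        "estimate": est, "se": se, "z": z,
        "p": 2 * stats.norm.sf(np.abs(z)),
        "term": [_term_of(n) for n in names]}, index=names)
    n_obs = int(_scalar(out["n_obs"]))
    anova = _wald_table(coef, vcov, n_obs)
    singular = bool(_scalar(out["singular"]))
    converged = bool(_scalar(out["converged"]))
    if singular:
        logger.warning("random-effects covariance is singular; SEs may be "
                       "unreliable (structure: %s)", out["random_formula"])
    return MixedFitResult(
        coefficients=coef, anova=anova, re_variance=out.get("re_variance", {}),
        converged=converged, singular=singular, n_rows=n_obs,
        formula=fixed, random_formula=str(_scalar(out["random_formula"])),
        backend=backend, messages=list(np.atleast_1d(out.get("messages", []))))


class MixedLogisticStay(BaseEstimator):
    """Hierarchical logistic regression of stay/switch behaviour.

    Fixed effects: reward * transition, crossed with the session factor
    when more than one session is present (treatment coding, first
    session as reference); optionally a ``correct`` regressor. Random
    effects per subject: intercept and reward/transition/interaction
    slopes, simplified down a fallback ladder on convergence failure.
    Backend: ``lme4::glmer`` (Laplace approximation).
    """

    def __init__(self, include_correct=False, include_sessions="auto",
                 random_effects="full"):
        self.include_correct = include_correct
        self.include_sessions = include_sessions
        self.random_effects = random_effects

    def _formulas(self, design: pd.DataFrame):
        multi = design["session"].nunique() > 1
        use_sessions = multi if self.include_sessions == "auto" else self.include_sessions
        fixed = "stay ~ reward * transition"
        if use_sessions:
            fixed += " * session"
        re_core = "1 + reward * transition"
        if self.include_correct:
            fixed += " + correct"
            re_core += " + correct"
        ladder = {
            "full": [f"({re_core} | subject)",
                     f"({re_core} || subject)",
                     "(1 | subject)"],
            "diagonal": [f"({re_core} || subject)", "(1 | subject)"],
            "intercept": ["(1 | subject)"],
        }[self.random_effects]
        return fixed, ladder

    def fit(self, design: pd.DataFrame, y=None):
        if design["subject"].nunique() < 2:
            raise ValueError("mixed model needs >= 2 subjects")
        if not set(np.unique(design["stay"])) <= {0, 1}:
            raise ValueError("stay outcome must be binary")
        fixed, ladder = self._formulas(design)
        out = _lme4.run_mixed_model(design, fixed, ladder, family="binomial")
        self.result_ = _result_from_lme4(out, fixed, backend="lme4::glmer")
        return self


class MixedLinearResponse(BaseEstimator):
    """Linear mixed model for continuous per-trial responses.

    Same fixed/random structure as the logistic stay model, Gaussian
    likelihood profiled by REML (statsmodels MixedLM). The response is
    z-scored within subject by default.
    """

    def __init__(self, response_col="response", include_correct=False,
                 include_sessions="auto", random_effects="full",
                 scale_response=True):
        self.response_col = response_col
        self.include_correct = include_correct
        self.include_sessions = include_sessions
        self.random_effects = random_effects
        self.scale_response = scale_response

    def fit(self, design: pd.DataFrame, y=None):
        import statsmodels.formula.api as smf

        design = design.copy()
        resp = self.response_col
        if resp not in design:
            raise ValueError(f"design has no column {resp!r}")
        if np.allclose(design[resp].var(), 0.0):
            raise ValueError("response has zero variance")
        if self.scale_response:
            design[resp] = (design.groupby("subject")[resp]
                            .transform(lambda x: (x - x.mean()) / x.std(ddof=0)))
        multi = design["session"].nunique() > 1
        use_sessions = multi if self.include_sessions == "auto" else self.include_sessions
        fixed = f"{resp} ~ reward * transition"
        if use_sessions:
            fixed += " * C(session)"
        re_full = "1 + reward + transition + reward:transition"
        if self.include_correct:
            fixed += " + correct"
            re_full += " + correct"
        ladder = [re_full, "1"] if self.random_effects == "full" else ["1"]
        fit = None
        singular = False
        used = ladder[-1]
        for re_formula in ladder:
            try:
                import warnings as _w
                with _w.catch_warnings(record=True) as caught:
                    _w.simplefilter("always")
                    model = smf.mixedlm(fixed, design, groups=design["subject"],
                                        re_formula=re_formula)
                    cand = model.fit(reml=True, maxiter=500)
                conv_problem = any("converge" in str(c.message).lower()
                                   for c in caught)
                sing = any("singular" in str(c.message).lower() for c in caught)
                if cand is not None and not conv_problem:
                    fit, used, singular = cand, re_formula, sing
                    break
                if fit is None and cand is not None:
                    fit, used, singular = cand, re_formula, True
            except Exception as exc:  # noqa: BLE001 - try simpler structure
                logger.warning("re_formula %r failed (%s); simplifying", re_formula, exc)
        if fit is None:
            raise RuntimeError("linear mixed model failed for all structures")
        if used != ladder[0]:
            logger.warning("random-effects structure simplified to %r", used)
        fe = fit.fe_params
        names = list(fe.index)
        vcov = np.asarray(fit.cov_params().loc[names, names])
        est = fe.to_numpy()
        diag = np.diag(vcov)
        se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        z = est / se
        coef = pd.DataFrame({
            "estimate": est, "se": se, "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
            "term": [_term_of(n) for n in names]}, index=names)
        coef = coef.rename(index={"Intercept": "(Intercept)"})
        anova = _wald_table(coef, vcov, len(design))
        self.result_ = MixedFitResult(
            coefficients=coef, anova=anova,
            re_variance={"cov_re": np.asarray(fit.cov_re).tolist()},
            converged=bool(fit.converged), singular=singular,
            n_rows=len(design), formula=fixed, random_formula=used,
            backend="statsmodels::MixedLM")
        return self


def fit_mixed_logistic(design: pd.DataFrame, include_correct=False,
                       include_sessions="auto", random_effects="full") -> MixedFitResult:
    """Functional wrapper over :class:`MixedLogisticStay`."""
    est = MixedLogisticStay(include_correct=include_correct,
                            include_sessions=include_sessions,
                            random_effects=random_effects)
    return est.fit(design).result_


def fit_mixed_linear(design: pd.DataFrame, response_col="response",
                     **kwargs) -> MixedFitResult:
    """Functional wrapper over :class:`MixedLinearResponse`."""
    est = MixedLinearResponse(response_col=response_col, **kwargs)
    return est.fit(design).result_


_CELLS = [("R+C", 1, 1), ("R+U", 1, -1), ("R-C", -1, 1), ("R-U", -1, -1)]


def stay_probability_summary(design: pd.DataFrame) -> pd.DataFrame:
    """p(stay) per {rewarded, unrewarded} x {common, uncommon} cell.

    Cell means are averages of per-subject means, with the SE over
    subjects; reported per session and pooled across sessions. Empty
    cells come back as NaN, not zero.
    """
    blocks = [("pooled", design)] + [
        (s, g) for s, g in design.groupby("session", sort=True)]
    rows = []
    for label, block in blocks:
        for cell, r, t in _CELLS:
            sel = block[(block.reward == r) & (block.transition == t)]
            per_subj = sel.groupby("subject")["stay"].mean()
            n = len(per_subj)
            rows.append({
                "session": label, "cell": cell,
                "p_stay": per_subj.mean() if n else np.nan,
                "se": per_subj.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_subjects": n})
    return pd.DataFrame(rows)


def coefficient_correlation(result_a, result_b):
    """Pearson r (and p) between two fits' matched coefficient vectors."""
    a = result_a.coefficients["estimate"] if isinstance(result_a, MixedFitResult) else pd.Series(result_a)
    b = result_b.coefficients["estimate"] if isinstance(result_b, MixedFitResult) else pd.Series(result_b)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 matched coefficients, got {len(common)}")
    r, p = stats.pearsonr(a.loc[common], b.loc[common])
    return float(r), float(p)


def logistic_null_calibration(n_replicates=500, n_subjects=12, n_rows=60,
                              alpha=0.05, seed=None) -> dict:
    """Type-I error of the glmer Wald test for 'reward' under the null.

    Simulates cohorts where stay is an unbiased coin independent of the
    regressors, fits ``stay ~ reward * transition + (1 | subject)`` per
    replicate (batched in one R call) and returns the rejection rate of
    the reward term at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    n = n_replicates * n_subjects * n_rows
    df = pd.DataFrame({
        "replicate": np.repeat(np.arange(n_replicates), n_subjects * n_rows),
        "subject": np.tile(np.repeat(np.arange(n_subjects), n_rows), n_replicates),
        "stay": rng.integers(0, 2, size=n),
        "reward": rng.choice([-1, 1], size=n),
        "transition": rng.choice([-1, 1], size=n)})
    pvals = np.asarray(_lme4.run_glmer_null_batch(
        df, "stay ~ reward * transition + (1 | subject)", "reward"), dtype=float)
    ok = np.isfinite(pvals)
    return {"rejection_rate": float((pvals[ok] < alpha).mean()),
            "n_effective": int(ok.sum()), "pvalues": pvals}
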