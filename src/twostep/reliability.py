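"""Test-retest reliability, repeated-measures statistics and power.

Reliability of a subjects x sessions quantity is summarised by the
Shrout–Fleiss ICC(2,k) — a two-way random-effects, absolute-agreement,
mean-of-k-ratings intraclass correlation (poor < 0.4, moderate
0.4–0.75, excellent > 0.75) — and repeatability by the coefficient of
variation (SD over the absolute mean, in percent). Session effects are
tested by one-way repeated-measures ANOVA with Bonferroni-corrected
pairwise comparisons and orthogonal polynomial contrasts. The power
module simulates linear training effects on a parameter with a given
test-retest reliability and inverts the power curve for the minimal
detectable fractional change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .fitting import REFERENCE_PRIOR
from .hybrid import NATURAL7

__all__ = [
    "SubjectSessionMatrix", "PowerSpec", "icc_2k", "cv_percent",
    "rm_anova", "pearson_table", "power_simulation", "detectable_effect",
    "polynomial_contrasts", "reference_param_distribution",
]


@dataclass(frozen=True)
class SubjectSessionMatrix:
    """A subjects x sessions matrix of one quantity."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 sessions")
        if not np.all(np.isfinite(v)):
            raise ValueError("missing entries are not allowed")
        object.__setattr__(self, "values", v)

    def to_long(self) -> pd.DataFrame:
        n, k = self.values.shape
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "session": np.tile(np.arange(1, k + 1), n),
            "value": self.values.ravel()})


def _as_matrix(matrix) -> SubjectSessionMatrix:
    if isinstance(matrix, SubjectSessionMatrix):
        return matrix
    return SubjectSessionMatrix(np.asarray(matrix, dtype=float))


def icc_label(icc: float) -> str:
    return "poor" if icc < 0.4 else "moderate" if icc <= 0.75 else "excellent"


def icc_2k(matrix) -> dict:
    """ICC(2,k) with 95% CI, the F test of ICC = 0 and a qualitative label."""
    m = _as_matrix(matrix)
    if np.allclose(m.values.var(), 0.0):
        raise ValueError("zero total variance; ICC undefined")
    resid = m.values - m.values.mean(axis=1, keepdims=True) \
        - m.values.mean(axis=0, keepdims=True) + m.values.mean()
    if np.allclose(resid, 0.0) and np.allclose(m.values.std(axis=0), m.values.std(axis=0).mean()):
        # degenerate perfect agreement: zero error variance
        return {"icc": 1.0, "ci": (1.0, 1.0), "p": 0.0, "F": np.inf,
                "df1": m.values.shape[0] - 1.0,
                "df2": float((m.values.shape[0] - 1) * (m.values.shape[1] - 1)),
                "label": "excellent"}
    table = pg.intraclass_corr(data=m.to_long(), targets="subject",
                               raters="session", ratings="value")
    row = table[table["Type"] == "ICC(A,k)"].iloc[0]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lb, ub = (float(x) for x in row[ci_col])
    return {"icc": icc, "ci": (lb, ub), "p": float(row["pval"]),
            "F": float(row["F"]), "df1": float(row["df1"]),
            "df2": float(row["df2"]), "label": icc_label(icc)}


def cv_percent(matrix, n_boot: int = 2000, seed=None) -> dict:
    """Coefficient of variation in percent, with a bootstrap CI.

    Computed per subject across sessions (sample SD over the absolute
    subject mean) and aggregated as the mean over subjects; the 95% CI
    resamples subjects.
    """
    m = _as_matrix(matrix)
    means = m.values.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("a subject mean is exactly zero; CV undefined")
    per_subject = m.values.std(axis=1, ddof=1) / np.abs(means)
    cv = 100.0 * per_subject.mean()
    rng = np.random.default_rng(seed)
    n = per_subject.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = 100.0 * per_subject[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"cv": float(cv), "ci": (float(lo), float(hi)),
            "per_subject": per_subject * 100.0}


def polynomial_contrasts(n_levels: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix, rows = degree 1..n-1."""
    x = np.arange(n_levels, dtype=float)
    v = np.vander(x, n_levels, increasing=True)
    q, _ = np.linalg.qr(v)
    c = q[:, 1:].T
    # fix sign so the linear contrast increases with the level
    for row in c:
        if row[-1] < 0:
            row *= -1
    return c


_POLY_NAMES = ["linear", "quadratic", "cubic", "quartic", "quintic"]


def rm_anova(matrix, gg_correction: bool = False) -> dict:
    """One-way repeated-measures ANOVA over sessions.

    Returns the omnibus F test, all Bonferroni-corrected pairwise
    session comparisons and t tests of the orthogonal polynomial
    contrasts (linear .. degree k-1). ``gg_correction`` reports the
    Greenhouse-Geisser corrected p-value instead of the uncorrected
    one (off by default; no sphericity correction is assumed).
    """
    m = _as_matrix(matrix)
    long = m.to_long()
    aov = pg.rm_anova(data=long, dv="value", within="session",
                      subject="subject", detailed=False,
                      correction=gg_correction)
    row = aov.iloc[0]
    pairwise = pg.pairwise_tests(data=long, dv="value", within="session",
                                 subject="subject", padjust="bonf")
    k = m.values.shape[1]
    contrasts = polynomial_contrasts(k)
    crows = []
    for degree, c in enumerate(contrasts, start=1):
        scores = m.values @ c
        t, p = stats.ttest_1samp(scores, 0.0)
        crows.append({"contrast": _POLY_NAMES[degree - 1] if degree <= 5 else f"deg{degree}",
                      "t": float(t), "df": scores.size - 1, "p": float(p)})
    p = float(row["p_GG_corr"]) if gg_correction else float(row["p_unc"])
    return {"F": float(row["F"]), "df1": float(row["ddof1"]),
            "df2": float(row["ddof2"]), "p": p,
            "anova": aov, "pairwise": pairwise,
            "contrasts": pd.DataFrame(crows)}


def pearson_table(x: pd.DataFrame, y: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p for every (column of x) x (column of y) pair."""
    x = pd.DataFrame(x)
    y = pd.DataFrame(y)
    rows = []
    for cx in x.columns:
        for cy in y.columns:
            r, p = stats.pearsonr(x[cx], y[cy])
            rows.append({"x": cx, "y": cy, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def reference_param_distribution(which: str) -> tuple[float, float]:
    """Natural-scale (mean, SD) of a beta parameter implied by the
    synthetic reference population (log-normal on the natural scale)."""
    j = NATURAL7.index(which)
    mu, s2 = REFERENCE_PRIOR.mean[j], REFERENCE_PRIOR.var[j]
    mean = float(np.exp(mu + s2 / 2.0))
    sd = float(mean * np.sqrt(np.expm1(s2)))
    return mean, sd


@dataclass(frozen=True)
class PowerSpec:
    """Monte-Carlo power analysis settings.

    ``effect`` is the fractional linear change of the group mean from
    the first to the last session (0.8 = +80%). ``reliability`` splits
    the parameter variance into a stable subject trait (fraction
    ``reliability``) and independent session noise; training shifts the
    mean linearly and leaves the variance untouched.
    """

    n_subjects: int = 20
    n_sessions: int = 5
    effect: float = 0.0
    reliability: float = 0.0
    alpha: float = 0.05
    n_replicates: int = 2000
    mean: float = None
    sd: float = None
    parameter: str = "bmf"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.reliability < 1.0):
            raise ValueError("reliability must lie in [0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.mean is None or self.sd is None:
            mean, sd = reference_param_distribution(self.parameter)
            object.__setattr__(self, "mean", self.mean if self.mean is not None else mean)
            object.__setattr__(self, "sd", self.sd if self.sd is not None else sd)


def power_simulation(spec: PowerSpec) -> float:
    """Monte-Carlo power of the linear-contrast test for a training trend.

    Per replicate, per-subject session values are drawn with the
    between/within variance split implied by ``reliability`` and the
    linear mean change given by ``effect``; the session trend is tested
    with a two-sided one-sample t test of the per-subject linear
    contrast scores at level ``alpha``. Returns the rejection rate.
    """
    rng = np.random.default_rng(spec.seed)
    n, k, reps = spec.n_subjects, spec.n_sessions, spec.n_replicates
    sd_between = spec.sd * np.sqrt(spec.reliability)
    sd_within = spec.sd * np.sqrt(1.0 - spec.reliability)
    grid = np.arange(k) / (k - 1)
    session_mean = spec.mean * (1.0 + spec.effect * grid)
    values = (session_mean
              + sd_between * rng.standard_normal((reps, n, 1))
              + sd_within * rng.standard_normal((reps, n, k)))
    c = polynomial_contrasts(k)[0]
    scores = values @ c                      # (reps, n)
    t = scores.mean(axis=1) / (scores.std(axis=1, ddof=1) / np.sqrt(n))
    crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df=n - 1)
    return float((np.abs(t) > crit).mean())


def detectable_effect(spec: PowerSpec, target_power: float = 0.8,
                      max_effect: float = 10.0, tol: float = 1e-3) -> float:
    """Minimal fractional change reaching ``target_power``, by bisection.

    Relies on power being monotone in the effect size; the replicate
    noise is held fixed across bisection steps via the spec seed.
    """
    from dataclasses import replace

    lo, hi = 0.0, max_effect
    if power_simulation(replace(spec, effect=hi)) < target_power:
        raise ValueError(f"target power not reachable below effect={max_effect}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_simulation(replace(spec, effect=mid)) >= target_power:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
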