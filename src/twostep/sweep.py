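"""Mapping hybrid-model parameters onto one-trial-back regression effects.

Each of the seven agent parameters is swept over a five-point grid
while the other six stay clamped at reference medians; cohorts of
simulated agents per grid value are pushed through the stay/switch
regression, and the Pearson correlation between the grid and the fitted
'reward' (model-free index, MF_CI) or 'reward x transition'
(model-based index, MB_CI) coefficients summarises how strongly that
parameter drives each one-step effect. The mapping is deliberately
one-way: regression coefficients conflate several parameters, so no
inverse operation is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .fitting import REFERENCE_PRIOR
from .hybrid import NATURAL7, get_variant
from .regression import build_stay_design, fit_mixed_logistic
from .task import TaskConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["SweepSpec", "DEFAULT_GRIDS", "DEFAULT_MEDIANS", "run_sweep",
           "run_all_sweeps", "correlation_indices", "reconstruct_lme"]

#: Reference five-point grids per parameter (natural scale), spanning the
#: 5th..95th percentile range of a plausible fitted population; fully
#: configurable per sweep.
DEFAULT_GRIDS: dict[str, list[float]] = {
    "bmb": [0.25, 0.5, 1.0, 2.0, 4.0],
    "bmf": [0.25, 0.5, 1.0, 2.0, 4.0],
    "beta2": [0.25, 0.5, 1.0, 2.0, 4.0],
    "alpha1": [0.1, 0.3, 0.5, 0.7, 0.9],
    "alpha2": [0.1, 0.3, 0.5, 0.7, 0.9],
    "lam": [0.1, 0.3, 0.5, 0.7, 0.9],
    "p": [-0.5, -0.15, 0.0, 0.15, 0.5],
}

#: Clamped values for the non-swept parameters: the grid centres.
DEFAULT_MEDIANS: dict[str, float] = {
    "bmb": 1.0, "bmf": 1.0, "beta2": 1.0,
    "alpha1": 0.5, "alpha2": 0.5, "lam": 0.5, "p": 0.0,
}

_COEF_MAP = {"Intercept": "(Intercept)", "reward": "reward",
             "transition": "transition",
             "reward_x_transition": "reward:transition"}


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: grid, clamped medians and cohort size."""

    parameter: str
    grid: tuple = None
    medians: dict = None
    n_subjects: int = 1000
    n_trials: int = 201
    seed: int = 0

    def __post_init__(self):
        if self.parameter not in NATURAL7:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        grid = tuple(self.grid if self.grid is not None
                     else DEFAULT_GRIDS[self.parameter])
        diffs = np.diff(grid)
        if len(grid) < 2 or not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("grid must be strictly monotone with >= 2 points")
        if self.n_subjects % len(grid):
            raise ValueError("n_subjects must be divisible by the grid length")
        object.__setattr__(self, "grid", grid)
        med = dict(DEFAULT_MEDIANS)
        med.update(self.medians or {})
        object.__setattr__(self, "medians", med)


def _pooled_logistic(design: pd.DataFrame) -> pd.DataFrame:
    """Pooled (fixed-effects only) logistic fit of the stay design.

    Within a sweep grid point all agents share the same parameters, so
    there is no true between-subject heterogeneity and the pooled GLM
    targets the same coefficients as the hierarchical fit at a fraction
    of the cost.
    """
    x = pd.DataFrame({
        "Intercept": 1.0,
        "reward": design["reward"].astype(float),
        "transition": design["transition"].astype(float),
        "reward_x_transition": (design["reward"] * design["transition"]).astype(float),
    })
    fit = sm.GLM(design["stay"].to_numpy(), x, family=sm.families.Binomial()).fit()
    return pd.DataFrame({"estimate": fit.params, "se": fit.bse})


def run_sweep(spec: SweepSpec, config: TaskConfig = None,
              method: str = "pooled") -> pd.DataFrame:
    """Simulate and fit the stay regression at every grid value.

    Returns one row per grid value with the four coefficient estimates
    and their SEs. ``method`` is "pooled" (default) or "mixed" (the
    hierarchical logistic used for the main analysis).
    """
    config = config or TaskConfig(n_trials=spec.n_trials)
    n_per = spec.n_subjects // len(spec.grid)
    rows = []
    for gi, value in enumerate(spec.grid):
        pars = dict(spec.medians)
        pars[spec.parameter] = value
        tab = pd.DataFrame({"subject": np.arange(n_per) + gi * n_per,
                            "session": 1})
        for k in NATURAL7:
            tab[k] = pars[k]
        cohort = simulate_cohort(tab, config, seed=spec.seed)
        design = build_stay_design(cohort)
        if method == "pooled":
            coefs = _pooled_logistic(design)
            get = lambda key: coefs.loc[key]
        else:
            res = fit_mixed_logistic(design, include_sessions=False)
            get = lambda key: res.coefficients.loc[_COEF_MAP[key]]
        row = {"parameter": spec.parameter, "grid_value": value}
        for key in ("Intercept", "reward", "transition", "reward_x_transition"):
            c = get(key)
            row[f"coef_{key}"] = float(c["estimate"])
            row[f"se_{key}"] = float(c["se"])
        rows.append(row)
    return pd.DataFrame(rows)


def run_all_sweeps(parameters=NATURAL7, n_subjects: int = 1000,
                   n_trials: int = 201, seed: int = 0, grids=None,
                   medians=None, method: str = "pooled") -> pd.DataFrame:
    """Run :func:`run_sweep` for several parameters; seeds are derived
    per parameter from the master seed."""
    grids = grids or {}
    frames = []
    master = np.random.SeedSequence(seed)
    for par, child in zip(parameters, master.spawn(len(parameters))):
        spec = SweepSpec(parameter=par, grid=grids.get(par),
                         medians=medians, n_subjects=n_subjects,
                         n_trials=n_trials,
                         seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        frames.append(run_sweep(spec, method=method))
        logger.info("sweep finished for %s", par)
    return pd.concat(frames, ignore_index=True)


def correlation_indices(sweep_results: pd.DataFrame) -> pd.DataFrame:
    """MF_CI / MB_CI per parameter from sweep results.

    MF_CI is the Pearson correlation between the grid values and the
    fitted 'reward' coefficients; MB_CI the same for the
    'reward x transition' coefficients. A coefficient series with zero
    variance yields an undefined (NaN) index, never 0.
    """
    rows = []
    for par, g in sweep_results.groupby("parameter", sort=False):
        if len(g) < 3:
            raise ValueError(f"parameter {par}: need >= 3 grid points")
        out = {"parameter": par}
        for label, col in (("MF_CI", "coef_reward"),
                           ("MB_CI", "coef_reward_x_transition")):
            y = g[col].to_numpy()
            if np.allclose(y.var(), 0.0):
                logger.warning("%s: zero coefficient variance, %s undefined",
                               par, label)
                out[label] = np.nan
            else:
                out[label] = float(stats.pearsonr(g["grid_value"], y).statistic)
        rows.append(out)
    return pd.DataFrame(rows).set_index("parameter")


#: Parameters whose reconstruction loads on the model-free ('reward')
#: versus model-based ('reward x transition') coefficient.
MF_RECON_PARAMS = ("bmf", "alpha1", "lam")
MB_RECON_PARAMS = ("bmb", "beta2", "alpha2")


def reconstruct_lme(session_means: pd.DataFrame,
                    indices: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct per-session MF/MB coefficient patterns from indices.

    ``session_means`` holds the fitted natural-scale parameter means per
    session (rows: parameter, columns: session). The reconstruction sums
    index * mean over {bMF, alpha1, lambda} for the MF pattern and over
    {bMB, beta2, alpha2} for the MB pattern, reported relative to the
    first session.
    """
    needed = set(MF_RECON_PARAMS + MB_RECON_PARAMS)
    if not needed <= set(session_means.index):
        raise ValueError(f"session_means missing parameters: "
                         f"{sorted(needed - set(session_means.index))}")
    if session_means.isna().any().any():
        raise ValueError("session_means contains missing values")
    mf = sum(indices.loc[p, "MF_CI"] * session_means.loc[p]
             for p in MF_RECON_PARAMS)
    mb = sum(indices.loc[p, "MB_CI"] * session_means.loc[p]
             for p in MB_RECON_PARAMS)
    out = pd.DataFrame({"MF_recon": mf, "MB_recon": mb})
    return out - out.iloc[0]
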