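import numpy as np
import pandas as pd
import pytest

from twostep.fitting import sample_cohort_params
from twostep.task import TaskConfig, simulate_cohort, simulate_session


NATURAL7 = ("bmb", "bmf", "beta2", "alpha1", "alpha2", "lam", "p")


def param_table(n_subjects, n_sessions=1, **overrides):
    """Constant-parameter cohort table with optional overrides."""
    base = dict(bmb=1.0, bmf=1.0, beta2=2.0, alpha1=0.5, alpha2=0.5,
                lam=0.5, p=0.1)
    base.update(overrides)
    tab = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subjects), n_sessions),
        "session": np.tile(np.arange(1, n_sessions + 1), n_subjects)})
    for k in NATURAL7:
        tab[k] = base[k]
    return tab


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_config():
    return TaskConfig(n_trials=60)


@pytest.fixture(scope="session")
def one_session(config):
    """A single 201-trial session from a typical mixed MF/MB agent."""
    return simulate_session(
        dict(bmb=1.5, bmf=1.0, beta2=2.5, alpha1=0.5, alpha2=0.5, lam=0.5, p=0.2),
        config, seed=42)


@pytest.fixture(scope="session")
def small_cohort(short_config):
    """8 heterogeneous subjects x 1 session x 60 trials."""
    tab = sample_cohort_params(8, 1, seed=3)
    return simulate_cohort(tab, short_config, seed=4)
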