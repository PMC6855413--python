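"""Generative model of the two-step decision task and synthetic-cohort I/O.

The task: on every trial the agent makes a stage-1 choice between two
actions; each action leads to one of two stage-2 states — its "common"
state with probability ``p_common`` (default 0.7) and the other state
otherwise. In the stage-2 state the agent chooses between two options,
each paying a unit reward with a probability that drifts across trials
as a Gaussian random walk reflected into ``[walk_lo, walk_hi]``
(default 0.25–0.75, step SD 0.025). The common mapping is the identity:
stage-1 action ``k`` commonly leads to stage-2 state ``k``.

Cohorts are simulated in closed loop with the seven-parameter hybrid
model-free/model-based agent (see :mod:`twostep.hybrid`). Sessions are
stored column-wise as small integer arrays; per-trial records are
materialised on demand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "SessionData",
    "generate_reward_walk",
    "sample_transition",
    "simulate_session",
    "simulate_cohort",
    "read_trials",
    "write_trials",
    "cohort_to_frame",
]

#: CSV columns of the trial interchange format.
TRIAL_COLUMNS = [
    "subject", "session", "trial", "choice1", "state2", "choice2",
    "transition", "reward", "rt1", "rt2", "missed",
]

# log-normal response-time model used for synthetic rt1/rt2 (seconds)
_RT_LOG_MU = np.log(0.65)
_RT_LOG_SD = 0.25


class ConfigurationError(ValueError):
    """Raised for invalid task configurations."""


class TrialFormatError(ValueError):
    """Raised when a trial file violates the interchange format."""


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step task generative process.

    Defaults reproduce the standard design: 201 trials per session,
    70/30 transition scheme, reward-probability random walks with step
    SD 0.025 reflected into [0.25, 0.75].
    """

    n_trials: int = 201
    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_lo: float = 0.25
    walk_hi: float = 0.75
    walk_init: np.ndarray | None = None  # (n_states, n_actions) or None -> uniform draw
    n_stage2_states: int = 2
    n_actions_per_state: int = 2
    reward_value: float = 0.2
    response_deadline_s: float = 2.0
    miss_rate: float = 0.0

    def __post_init__(self):
        if not self.walk_lo < self.walk_hi:
            raise ConfigurationError(
                f"walk_lo must be < walk_hi (got {self.walk_lo}, {self.walk_hi})")
        if not (0.0 < self.walk_lo and self.walk_hi < 1.0):
            raise ConfigurationError("walk boundaries must lie in (0, 1)")
        if self.walk_sd < 0:
            raise ConfigurationError("walk_sd must be >= 0")
        if not (0.5 < self.p_common <= 1.0):
            raise ConfigurationError("p_common must lie in (0.5, 1]")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ConfigurationError("miss_rate must lie in [0, 1)")
        if self.n_stage2_states != 2 or self.n_actions_per_state != 2:
            raise ConfigurationError(
                "only the 2-state x 2-action second stage is supported")
        if self.walk_init is not None:
            init = np.asarray(self.walk_init, dtype=float)
            if init.shape != (self.n_stage2_states, self.n_actions_per_state):
                raise ConfigurationError(
                    "walk_init must have shape (n_stage2_states, n_actions_per_state)")
            if np.any(init < self.walk_lo) or np.any(init > self.walk_hi):
                raise ConfigurationError("walk_init values must lie in [walk_lo, walk_hi]")
            object.__setattr__(self, "walk_init", init)


@dataclass(frozen=True)
class RewardWalk:
    """Reward probabilities indexed (trial, stage-2 state, stage-2 action)."""

    probs: np.ndarray
    lo: float = 0.25
    hi: float = 0.75

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class TrialRecord:
    """A single two-step trial. Missed trials carry no choices (-1 codes)."""

    subject_id: int
    session: int
    trial_index: int
    choice1: int
    state2: int
    choice2: int
    transition: str  # "common" | "uncommon"
    reward: int
    rt1_s: float
    rt2_s: float
    missed: bool


@dataclass
class SessionData:
    """One subject x session of trials, stored column-wise.

    ``choice1/state2/choice2/reward`` use -1 for missed trials. ``walk``
    is present only for synthetic data.
    """

    subject_id: int
    session: int
    choice1: np.ndarray
    state2: np.ndarray
    choice2: np.ndarray
    reward: np.ndarray
    missed: np.ndarray
    rt1: np.ndarray
    rt2: np.ndarray
    walk: RewardWalk | None = None

    def __len__(self) -> int:
        return self.choice1.shape[0]

    @property
    def n_valid(self) -> int:
        return int((~self.missed).sum())

    @property
    def valid(self) -> np.ndarray:
        return ~self.missed

    @property
    def transition_common(self) -> np.ndarray:
        """Boolean per trial; False also for missed trials."""
        return (self.state2 == self.choice1) & ~self.missed

    def __getitem__(self, t: int) -> TrialRecord:
        if self.missed[t]:
            trans = ""
        else:
            trans = "common" if self.state2[t] == self.choice1[t] else "uncommon"
        return TrialRecord(
            subject_id=self.subject_id, session=self.session, trial_index=t,
            choice1=int(self.choice1[t]), state2=int(self.state2[t]),
            choice2=int(self.choice2[t]), transition=trans,
            reward=int(self.reward[t]), rt1_s=float(self.rt1[t]),
            rt2_s=float(self.rt2[t]), missed=bool(self.missed[t]))

    def trials(self) -> Iterable[TrialRecord]:
        return (self[t] for t in range(len(self)))


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by (possibly repeated) boundary reflection."""
    width = hi - lo
    z = np.mod(x - lo, 2.0 * width)
    z = np.where(z > width, 2.0 * width - z, z)
    return lo + z


def generate_reward_walk(config: TaskConfig, seed=None) -> RewardWalk:
    """Simulate reflected Gaussian random walks of reward probabilities.

    Each of the four stage-2 options evolves independently:
    ``p[t+1] = reflect(p[t] + N(0, walk_sd))`` into
    ``[walk_lo, walk_hi]``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shape = (config.n_stage2_states, config.n_actions_per_state)
    if config.walk_init is None:
        cur = rng.uniform(config.walk_lo, config.walk_hi, size=shape)
    else:
        cur = np.array(config.walk_init, dtype=float)
    probs = np.empty((config.n_trials,) + shape)
    probs[0] = cur
    if config.n_trials > 1:
        steps = rng.normal(0.0, config.walk_sd, size=(config.n_trials - 1,) + shape)
        for t in range(1, config.n_trials):
            cur = _reflect(cur + steps[t - 1], config.walk_lo, config.walk_hi)
            probs[t] = cur
    return RewardWalk(probs=probs, lo=config.walk_lo, hi=config.walk_hi)


def sample_transition(choice1: int, config: TaskConfig, rng=None):
    """Sample the stage-2 state for a stage-1 choice.

    Returns ``(state2, label)`` where the common mapping is the identity
    (action k commonly leads to state k) and ``label`` is ``"common"``
    or ``"uncommon"``.
    """
    if choice1 not in (0, 1):
        raise ValueError(f"choice1 must be 0 or 1, got {choice1}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if rng.random() < config.p_common:
        return choice1, "common"
    return 1 - choice1, "uncommon"


def _unit_rng(seed, subject: int, session: int) -> np.random.Generator:
    """Independent per-unit stream keyed by (seed, subject, session).

    Keying on the unit identity (not its position) makes cohort
    simulation invariant to row permutation of the parameter table.
    """
    ss = np.random.SeedSequence(entropy=int(seed) if seed is not None else None,
                                spawn_key=(int(subject), int(session)))
    return np.random.default_rng(ss)


def _simulate_batch(params7: np.ndarray, walks: np.ndarray, u: np.ndarray,
                    config: TaskConfig):
    """Closed-loop simulation of N agents for T trials (vectorised over agents).

    params7: (N, 7) natural-scale (bMB, bMF, beta2, alpha1, alpha2, lam, p).
    walks:   (N, T, 2, 2) reward probabilities.
    u:       (N, T, 7) iid uniforms consumed at fixed positions per trial
             (choice1, transition, choice2, reward, miss, rt1, rt2).
    """
    n, t_max = u.shape[0], u.shape[1]
    bmb, bmf, beta2 = params7[:, 0], params7[:, 1], params7[:, 2]
    a1, a2, lam, pers = params7[:, 3], params7[:, 4], params7[:, 5], params7[:, 6]
    pc = config.p_common

    q1 = np.zeros((n, 2))
    q2 = np.zeros((n, 2, 2))
    prev = np.full(n, -1)
    idx = np.arange(n)

    c1 = np.full((n, t_max), -1, dtype=np.int8)
    s2 = np.full((n, t_max), -1, dtype=np.int8)
    c2 = np.full((n, t_max), -1, dtype=np.int8)
    rew = np.full((n, t_max), -1, dtype=np.int8)
    missed = np.zeros((n, t_max), dtype=bool)

    for t in range(t_max):
        miss_t = u[:, t, 4] < config.miss_rate
        # stage 1: model-based values from the instructed transition scheme
        m0 = q2[:, 0].max(axis=1)
        m1 = q2[:, 1].max(axis=1)
        qmb0 = pc * m0 + (1 - pc) * m1
        qmb1 = pc * m1 + (1 - pc) * m0
        x0 = bmb * qmb0 + bmf * q1[:, 0] + pers * (prev == 0)
        x1 = bmb * qmb1 + bmf * q1[:, 1] + pers * (prev == 1)
        p_a0 = 1.0 / (1.0 + np.exp(x1 - x0))
        a = (u[:, t, 0] >= p_a0).astype(np.int8)
        common = u[:, t, 1] < pc
        s = np.where(common, a, 1 - a).astype(np.int8)
        # stage 2 softmax
        qs = q2[idx, s]
        p_b0 = 1.0 / (1.0 + np.exp(beta2 * (qs[:, 1] - qs[:, 0])))
        b = (u[:, t, 2] >= p_b0).astype(np.int8)
        r = (u[:, t, 3] < walks[idx, t, s, b]).astype(np.int8)

        ok = ~miss_t
        c1[ok, t] = a[ok]
        s2[ok, t] = s[ok]
        c2[ok, t] = b[ok]
        rew[ok, t] = r[ok]
        missed[miss_t, t] = True

        # SARSA(lambda) updates on valid trials only
        d1 = q2[idx, s, b] - q1[idx, a]
        d2 = r - q2[idx, s, b]
        upd1 = np.where(ok, a1 * (d1 + lam * d2), 0.0)
        q1[idx, a] += upd1
        q2[idx, s, b] += np.where(ok, a2 * d2, 0.0)
        prev = np.where(ok, a, prev)
    return c1, s2, c2, rew, missed


def _rts_from_uniform(u: np.ndarray, deadline: float) -> np.ndarray:
    """Synthetic log-normal response times truncated at the deadline."""
    rt = np.exp(_RT_LOG_MU + _RT_LOG_SD * ndtri(np.clip(u, 1e-12, 1 - 1e-12)))
    return np.minimum(rt, deadline - 1e-3)


def simulate_session(params, config: TaskConfig = TaskConfig(), seed=None,
                     subject_id: int = 0, session: int = 1) -> SessionData:
    """Simulate one closed-loop session of the hybrid agent.

    ``params`` is an :class:`~twostep.hybrid.AgentParams`, a mapping with
    the seven natural-scale fields, or a length-7 sequence
    (bMB, bMF, beta2, alpha1, alpha2, lam, p). Reward is coded 0/1 for
    the agent regardless of ``reward_value``. Bit-reproducible per seed.
    """
    from .hybrid import as_natural7

    rng = _unit_rng(seed, subject_id, session)
    walk = generate_reward_walk(config, seed=rng)
    u = rng.random((1, config.n_trials, 7))
    p7 = as_natural7(params)[None, :]
    c1, s2, c2, rew, missed = _simulate_batch(p7, walk.probs[None], u, config)
    rt1 = _rts_from_uniform(u[0, :, 5], config.response_deadline_s)
    rt2 = _rts_from_uniform(u[0, :, 6], config.response_deadline_s)
    rt1[missed[0]] = np.nan
    rt2[missed[0]] = np.nan
    return SessionData(subject_id=subject_id, session=session,
                       choice1=c1[0], state2=s2[0], choice2=c2[0], reward=rew[0],
                       missed=missed[0], rt1=rt1, rt2=rt2, walk=walk)


def simulate_cohort(param_table: pd.DataFrame, config: TaskConfig = TaskConfig(),
                    seed=None) -> list[SessionData]:
    """Simulate one session per row of ``param_table``.

    The table needs columns ``subject``, ``session`` and the seven
    natural-scale parameters ``bmb, bmf, beta2, alpha1, alpha2, lam, p``.
    Each unit gets an independent random stream derived from the master
    seed and its (subject, session) identity, so results are invariant
    to row order.
    """
    if len(param_table) == 0:
        raise ValueError("param_table is empty")
    needed = {"subject", "session", "bmb", "bmf", "beta2", "alpha1", "alpha2", "lam", "p"}
    missing = needed - set(param_table.columns)
    if missing:
        raise ValueError(f"param_table missing columns: {sorted(missing)}")

    n = len(param_table)
    t_max = config.n_trials
    walks = np.empty((n, t_max, 2, 2))
    u = np.empty((n, t_max, 7))
    rows = param_table.reset_index(drop=True)
    for i in range(n):
        rng = _unit_rng(seed, rows.at[i, "subject"], rows.at[i, "session"])
        walks[i] = generate_reward_walk(config, seed=rng).probs
        u[i] = rng.random((t_max, 7))
    p7 = rows[["bmb", "bmf", "beta2", "alpha1", "alpha2", "lam", "p"]].to_numpy(float)
    c1, s2, c2, rew, missed = _simulate_batch(p7, walks, u, config)
    rt1 = _rts_from_uniform(u[:, :, 5], config.response_deadline_s)
    rt2 = _rts_from_uniform(u[:, :, 6], config.response_deadline_s)
    rt1[missed] = np.nan
    rt2[missed] = np.nan

    sessions = []
    for i in range(n):
        sessions.append(SessionData(
            subject_id=int(rows.at[i, "subject"]), session=int(rows.at[i, "session"]),
            choice1=c1[i], state2=s2[i], choice2=c2[i], reward=rew[i],
            missed=missed[i], rt1=rt1[i], rt2=rt2[i],
            walk=RewardWalk(walks[i], config.walk_lo, config.walk_hi)))
    return sessions


def cohort_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Flatten sessions into the trial interchange table (0-based trials)."""
    frames = []
    for s in sessions:
        t = np.arange(len(s))
        common = s.state2 == s.choice1
        trans = np.where(s.missed, "", np.where(common, "common", "uncommon"))
        frames.append(pd.DataFrame({
            "subject": s.subject_id, "session": s.session, "trial": t,
            "choice1": s.choice1.astype(int), "state2": s.state2.astype(int),
            "choice2": s.choice2.astype(int), "transition": trans,
            "reward": s.reward.astype(int), "rt1": s.rt1, "rt2": s.rt2,
            "missed": s.missed.astype(int)}))
    return pd.concat(frames, ignore_index=True)


def write_trials(sessions: Sequence[SessionData], path) -> None:
    """Write sessions to CSV (UTF-8, header, columns of TRIAL_COLUMNS)."""
    df = cohort_to_frame(sessions)
    df.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> list[SessionData]:
    """Read a trial CSV back into sessions, validating codes row by row.

    Missed trials are preserved (choice/state/reward columns may be
    empty or -1 on those rows). Raises :class:`TrialFormatError` naming
    the first offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c not in ("rt1", "rt2")]
    if missing:
        raise TrialFormatError(f"missing required column(s): {missing}")
    if len(df) == 0:
        warnings.warn("trial file contains a header but no rows; empty cohort")
        logger.warning("empty trial file: %s", path)
        return []

    def _col(name, default=np.nan):
        return df[name] if name in df.columns else pd.Series(default, index=df.index)

    missed = _col("missed", 0).fillna(0).astype(int).to_numpy().astype(bool)
    ints = {}
    for name in ("choice1", "state2", "choice2", "reward"):
        v = pd.to_numeric(df[name], errors="coerce").fillna(-1).astype(int).to_numpy()
        ints[name] = v
    valid = ~missed
    for name, hi in (("choice1", 1), ("state2", 1), ("choice2", 1), ("reward", 1)):
        bad = valid & ((ints[name] < 0) | (ints[name] > hi))
        if bad.any():
            row = int(np.argmax(bad))
            raise TrialFormatError(
                f"row {row}: {name}={ints[name][row]} outside {{0,..,{hi}}}")
    trans = df["transition"].fillna("").astype(str).to_numpy()
    expect = np.where(ints["state2"] == ints["choice1"], "common", "uncommon")
    bad = valid & (trans != expect)
    if bad.any():
        row = int(np.argmax(bad))
        raise TrialFormatError(
            f"row {row}: transition label '{trans[row]}' inconsistent with "
            f"choice1={ints['choice1'][row]}, state2={ints['state2'][row]}")

    sessions = []
    for (subj, sess), g in df.groupby(["subject", "session"], sort=True):
        i = g.index.to_numpy()
        order = np.argsort(g["trial"].to_numpy())
        i = i[order]
        sessions.append(SessionData(
            subject_id=int(subj), session=int(sess),
            choice1=ints["choice1"][i].astype(np.int8),
            state2=ints["state2"][i].astype(np.int8),
            choice2=ints["choice2"][i].astype(np.int8),
            reward=ints["reward"][i].astype(np.int8),
            missed=missed[i],
            rt1=pd.to_numeric(_col("rt1"), errors="coerce").to_numpy()[i],
            rt2=pd.to_numeric(_col("rt2"), errors="coerce").to_numpy()[i],
            walk=None))
    return sessions
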