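"""The hybrid model-free / model-based agent and its variant family.

The winning variant (``ll2bmfbmb2alr``) has seven free parameters:

* ``bmb``, ``bmf`` — separate softmax weights for the model-based and
  model-free stage-1 values (both >= 0),
* ``beta2`` — stage-2 inverse temperature (>= 0),
* ``alpha1``, ``alpha2`` — stage-1/stage-2 learning rates in (0, 1),
* ``lam`` — SARSA(lambda) eligibility in (0, 1),
* ``p`` — perseveration (p > 0) or switching (p < 0), unbounded.

The original hybrid model (``llm2b2alr``) instead mixes the two systems
with a single stage-1 inverse temperature ``beta1`` and a weight
``omega`` in (0, 1); its stage-1 logit ``beta1*(omega*Q_MB +
(1-omega)*Q_MF)`` is algebraically the two-beta logit with
``bmb = beta1*omega`` and ``bmf = beta1*(1-omega)``. Every variant is
therefore reduced internally to the full natural 7-vector
(bMB, bMF, beta2, alpha1, alpha2, lam, p), with shared learning rates,
a missing eligibility trace (lam = 0) or missing perseveration (p = 0)
expressed as constraints.

Bounded parameters live on an unconstrained scale for fitting:
exponential transform for the betas, logistic for learning rates,
eligibility and omega, identity for p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from ._kernels import session_loglik7, session_loglik7_batch
from .task import SessionData, TaskConfig

__all__ = [
    "AgentParams", "ModelVariant", "VARIANTS", "QState",
    "transform_params", "inverse_transform_params", "as_natural7",
    "compute_qmb", "stage1_choice_probs", "stage2_choice_probs",
    "td_update", "session_loglik",
]

NATURAL7 = ("bmb", "bmf", "beta2", "alpha1", "alpha2", "lam", "p")


@dataclass(frozen=True)
class AgentParams:
    """Natural-scale parameters of the hybrid agent (full parameterisation)."""

    bmb: float
    bmf: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    p: float

    def __post_init__(self):
        if min(self.bmb, self.bmf, self.beta2) < 0:
            raise ValueError("betas must be >= 0")
        for name in ("alpha1", "alpha2", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def natural7(self) -> np.ndarray:
        return np.array([self.bmb, self.bmf, self.beta2, self.alpha1,
                         self.alpha2, self.lam, self.p])


def as_natural7(params) -> np.ndarray:
    """Coerce AgentParams / mapping / length-7 sequence to the natural 7-vector."""
    if isinstance(params, AgentParams):
        return params.natural7()
    if isinstance(params, Mapping):
        return np.array([float(params[k]) for k in NATURAL7])
    arr = np.asarray(params, dtype=float)
    if arr.shape != (7,):
        raise ValueError("expected 7 natural-scale parameters")
    return arr


@dataclass(frozen=True)
class ModelVariant:
    """A member of the hybrid-model family.

    ``param_names`` lists the variant's free parameters in vector order;
    ``transforms`` gives the unconstrained->natural map per parameter
    ("exp", "sigmoid" or "identity").
    """

    name: str
    two_beta: bool          # separate bMB/bMF vs beta1 + omega weighting
    separate_alphas: bool
    has_lambda: bool
    has_perseveration: bool

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["bmb", "bmf"] if self.two_beta else ["beta1", "omega"]
        names.append("beta2")
        names += ["alpha1", "alpha2"] if self.separate_alphas else ["alpha"]
        if self.has_lambda:
            names.append("lam")
        if self.has_perseveration:
            names.append("p")
        return tuple(names)

    @property
    def transforms(self) -> tuple[str, ...]:
        t = {"bmb": "exp", "bmf": "exp", "beta1": "exp", "beta2": "exp",
             "omega": "sigmoid", "alpha1": "sigmoid", "alpha2": "sigmoid",
             "alpha": "sigmoid", "lam": "sigmoid", "p": "identity"}
        return tuple(t[n] for n in self.param_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        """Map unconstrained vectors (..., d) to full natural 7-vectors (..., 7)."""
        u = np.asarray(u, dtype=float)
        if not np.all(np.isfinite(u)):
            raise ValueError("non-finite unconstrained parameters")
        if u.shape[-1] != self.n_params:
            raise ValueError(
                f"variant {self.name} expects {self.n_params} parameters, "
                f"got {u.shape[-1]}")
        vals = {}
        for i, (name, tr) in enumerate(zip(self.param_names, self.transforms)):
            x = u[..., i]
            if tr == "exp":
                vals[name] = np.exp(np.minimum(x, 30.0))  # overflow guard
            elif tr == "sigmoid":
                vals[name] = expit(x)
            else:
                vals[name] = x
        zeros = np.zeros(np.shape(u[..., 0]))
        if self.two_beta:
            bmb, bmf = vals["bmb"], vals["bmf"]
        else:
            bmb = vals["beta1"] * vals["omega"]
            bmf = vals["beta1"] * (1.0 - vals["omega"])
        if self.separate_alphas:
            a1, a2 = vals["alpha1"], vals["alpha2"]
        else:
            a1 = a2 = vals["alpha"]
        lam = vals["lam"] if self.has_lambda else zeros
        p = vals["p"] if self.has_perseveration else zeros
        return np.stack([bmb, bmf, vals["beta2"], a1, a2, lam, p], axis=-1)

    def from_natural(self, names_to_values: Mapping[str, float]) -> np.ndarray:
        """Variant-native natural values -> unconstrained vector."""
        out = np.empty(self.n_params)
        for i, (name, tr) in enumerate(zip(self.param_names, self.transforms)):
            v = float(names_to_values[name])
            out[i] = np.log(v) if tr == "exp" else logit(v) if tr == "sigmoid" else v
        return out


def _registry() -> dict[str, ModelVariant]:
    """Eight-variant family anchored by the winning two-beta model and the
    original weighted hybrid; the remaining six toggle shared learning
    rates, the eligibility trace and perseveration."""
    specs = [
        ("ll2bmfbmb2alr", True, True, True, True),    # winning variant (7)
        ("llm2b2alr", False, True, True, True),       # original hybrid (7)
        ("ll2bmfbmb2ar", True, True, False, True),
        ("ll2bmfbmb2al", True, True, True, False),
        ("ll2bmfbmbalr", True, False, True, True),
        ("llm2b2ar", False, True, False, True),
        ("llm2balr", False, False, True, True),
        ("llm2b2al", False, True, True, False),
    ]
    return {name: ModelVariant(name, tb, sa, hl, hp)
            for name, tb, sa, hl, hp in specs}


VARIANTS: dict[str, ModelVariant] = _registry()


def get_variant(variant) -> ModelVariant:
    if isinstance(variant, ModelVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise KeyError(
            f"unknown model variant {variant!r}; available: {sorted(VARIANTS)}")


def transform_params(unconstrained: Sequence[float], variant="ll2bmfbmb2alr") -> AgentParams:
    """Unconstrained vector -> natural-scale :class:`AgentParams`.

    exp for betas, logistic for rates/eligibility/omega, identity for p.
    """
    v = get_variant(variant)
    nat = v.to_natural(np.asarray(unconstrained, dtype=float))
    return AgentParams(*[float(x) for x in nat])


def inverse_transform_params(params, variant="ll2bmfbmb2alr") -> np.ndarray:
    """Natural-scale parameters -> unconstrained vector (log / logit / identity).

    ``params`` may be an AgentParams / 7-vector (full parameterisation,
    only valid for variants that can represent it) or a mapping of the
    variant's native parameter names.
    """
    v = get_variant(variant)
    if isinstance(params, Mapping) and not isinstance(params, AgentParams):
        return v.from_natural(params)
    nat = as_natural7(params)
    native = {}
    if v.two_beta:
        native["bmb"], native["bmf"] = nat[0], nat[1]
    else:
        native["beta1"] = nat[0] + nat[1]
        native["omega"] = nat[0] / native["beta1"]
    native["beta2"] = nat[2]
    if v.separate_alphas:
        native["alpha1"], native["alpha2"] = nat[3], nat[4]
    else:
        if not np.isclose(nat[3], nat[4]):
            raise ValueError(f"variant {v.name} shares alpha but alpha1 != alpha2")
        native["alpha"] = nat[3]
    if v.has_lambda:
        native["lam"] = nat[5]
    if v.has_perseveration:
        native["p"] = nat[6]
    return v.from_natural(native)


@dataclass
class QState:
    """Learned values carried across trials within a session."""

    q1_mf: np.ndarray        # (2,) stage-1 model-free values
    q2: np.ndarray           # (2, 2) stage-2 values per (state, action)
    prev_choice1: int = -1   # -1 before the first valid trial

    @classmethod
    def zeros(cls) -> "QState":
        return cls(q1_mf=np.zeros(2), q2=np.zeros((2, 2)))


def compute_qmb(q2: np.ndarray, p_common: float = 0.7) -> np.ndarray:
    """Model-based stage-1 values under the instructed transition scheme.

    Q_MB(a) = p_common * max_b q2[common_state(a), b]
            + (1 - p_common) * max_b q2[other_state(a), b]
    with the identity common mapping (action k -> state k).
    """
    q2 = np.asarray(q2, dtype=float)
    m = q2.max(axis=1)
    return np.array([p_common * m[0] + (1 - p_common) * m[1],
                     p_common * m[1] + (1 - p_common) * m[0]])


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def stage1_choice_probs(qstate: QState, params, variant="ll2bmfbmb2alr",
                        p_common: float = 0.7) -> np.ndarray:
    """Softmax stage-1 choice probabilities.

    Two-beta logit: bMB*Q_MB(a) + bMF*Q_MF(a) + p*1[a == prev_choice1];
    the omega variant is its reparameterisation. Perseveration is absent
    before the first valid trial (prev_choice1 == -1).
    """
    nat = as_natural7(params) if not isinstance(params, AgentParams) else params.natural7()
    qmb = compute_qmb(qstate.q2, p_common)
    x = nat[0] * qmb + nat[1] * qstate.q1_mf
    if qstate.prev_choice1 in (0, 1):
        x[qstate.prev_choice1] += nat[6]
    return _softmax(x)


def stage2_choice_probs(q2: np.ndarray, state2: int, beta2: float) -> np.ndarray:
    """Softmax over beta2 * q2[state2]; uniform for beta2 = 0."""
    return _softmax(beta2 * np.asarray(q2, dtype=float)[state2])


def td_update(qstate: QState, trial, params) -> QState:
    """Apply the SARSA(lambda) update for one (non-missed) trial in place.

    delta1 = q2[s2, c2] - q1[c1] (pre-update q2); q1[c1] += alpha1*delta1;
    delta2 = reward - q2[s2, c2]; q2[s2, c2] += alpha2*delta2;
    q1[c1] += alpha1*lam*delta2.
    """
    if getattr(trial, "missed", False):
        raise ValueError("td_update called on a missed trial; caller must skip it")
    nat = as_natural7(params) if not isinstance(params, AgentParams) else params.natural7()
    a1, a2, lam = nat[3], nat[4], nat[5]
    a, s, b, r = trial.choice1, trial.state2, trial.choice2, trial.reward
    d1 = qstate.q2[s, b] - qstate.q1_mf[a]
    qstate.q1_mf[a] += a1 * d1
    d2 = r - qstate.q2[s, b]
    qstate.q2[s, b] += a2 * d2
    qstate.q1_mf[a] += a1 * lam * d2
    qstate.prev_choice1 = a
    return qstate


def session_loglik(unconstrained, session: SessionData, variant="ll2bmfbmb2alr",
                   p_common: float = 0.7) -> float:
    """Log-likelihood of a session's choices at unconstrained parameters.

    Sums log P(choice1) + log P(choice2) over non-missed trials with the
    TD update applied after each; always <= 0 and deterministic.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    u = np.asarray(unconstrained, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite parameters")
    nat = get_variant(variant).to_natural(u)
    return float(session_loglik7(
        session.choice1, session.state2, session.choice2,
        session.reward.astype(np.float64), session.valid, nat, p_common))


def session_loglik_batch(unconstrained_matrix, session: SessionData,
                         variant="ll2bmfbmb2alr", p_common: float = 0.7) -> np.ndarray:
    """Vectorised :func:`session_loglik` over rows of a (K, d) matrix."""
    nat = get_variant(variant).to_natural(np.asarray(unconstrained_matrix, float))
    return session_loglik7_batch(
        session.choice1, session.state2, session.choice2,
        session.reward.astype(np.float64), session.valid,
        np.ascontiguousarray(nat), p_common)
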