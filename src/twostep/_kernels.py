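"""Numba-compiled likelihood kernels for the hybrid agent.

The session log-likelihood is the innermost loop of the empirical-Bayes
fitter and of the Monte-Carlo iBIC integral, so it is JIT-compiled. The
kernels operate on the full natural-scale 7-vector
(bMB, bMF, beta2, alpha1, alpha2, lam, p); every model variant reduces
to this parameterisation (see :mod:`twostep.hybrid`).
"""

import numpy as np
from numba import njit


@njit(fastmath=False)
def session_loglik7(c1, s2, c2, r, valid, theta, p_common):
    """Log-likelihood of one session's choices under the hybrid agent.

    Arrays are per-trial; ``valid[t]`` False marks missed trials, which
    contribute nothing and trigger no update. ``theta`` is the natural
    7-vector. Returns sum over valid trials of
    log P(choice1) + log P(choice2).
    """
    bmb, bmf, beta2 = theta[0], theta[1], theta[2]
    a1, a2, lam, pers = theta[3], theta[4], theta[5], theta[6]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    ll = 0.0
    for t in range(c1.shape[0]):
        if not valid[t]:
            continue
        m0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        m1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = p_common * m1 + (1.0 - p_common) * m0
        x0 = bmb * qmb0 + bmf * q1[0]
        x1 = bmb * qmb1 + bmf * q1[1]
        if prev == 0:
            x0 += pers
        elif prev == 1:
            x1 += pers
        a = c1[t]
        s = s2[t]
        b = c2[t]
        mx = x0 if x0 > x1 else x1
        lse = mx + np.log(np.exp(x0 - mx) + np.exp(x1 - mx))
        ll += (x0 if a == 0 else x1) - lse
        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        mx2 = y0 if y0 > y1 else y1
        lse2 = mx2 + np.log(np.exp(y0 - mx2) + np.exp(y1 - mx2))
        ll += (y0 if b == 0 else y1) - lse2
        # SARSA(lambda): delta1 uses the pre-update stage-2 value
        d1 = q2[s, b] - q1[a]
        q1[a] += a1 * d1
        d2 = r[t] - q2[s, b]
        q2[s, b] += a2 * d2
        q1[a] += a1 * lam * d2
        prev = a
    return ll


@njit(fastmath=False)
def session_loglik7_batch(c1, s2, c2, r, valid, thetas, p_common):
    """Log-likelihoods of one session under K parameter vectors (K, 7)."""
    k = thetas.shape[0]
    out = np.empty(k)
    for i in range(k):
        out[i] = session_loglik7(c1, s2, c2, r, valid, thetas[i], p_common)
    return out
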