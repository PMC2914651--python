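"""Compiled inner loop of the path evaluator (mass-action networks).

One function does the work the sampler spends nearly all its time on:
replay a candidate event sequence from its start state, accumulate the
complete-data log-likelihood and the per-reaction integrated propensities
``G_r = int h_r / theta_r dt`` in a single pass.  Falls back to the
vectorized numpy implementation for networks with custom rate laws.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = float("-inf")


@njit(cache=True, fastmath=False)
def mass_action_path_eval(A, ptr, spec, stoich, invfact, theta, x0, types, times, t0, t1):
    """Return ``(loglik, G)`` for one interval; ``loglik = -inf`` when any
    fired reaction has non-positive hazard at its firing state."""
    J = types.shape[0]
    M = A.shape[0]
    K = x0.shape[0]
    x = np.empty(K, dtype=np.int64)
    for a in range(K):
        x[a] = x0[a]
    G = np.zeros(M)
    g = np.empty(M)
    log_fired = 0.0
    t_prev = t0
    for j in range(J + 1):
        t_next = times[j] if j < J else t1
        dt = t_next - t_prev
        for r in range(M):
            f = invfact[r]
            for k in range(ptr[r], ptr[r + 1]):
                a = spec[k]
                u = stoich[k]
                for i in range(u):
                    f *= x[a] - i
            g[r] = f
            G[r] += f * dt
        if j < J:
            r = types[j]
            fired = theta[r] * g[r]
            if fired <= 0.0:
                return NEG_INF, G
            log_fired += np.log(fired)
            for a in range(K):
                x[a] += A[r, a]
        t_prev = t_next
    total = 0.0
    for r in range(M):
        total += theta[r] * G[r]
    return log_fired - total, G
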