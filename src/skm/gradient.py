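"""Likelihood-gradient estimation from sampled latent paths.

For a complete reaction path the log-likelihood is

    log pi(Xi | theta) = sum_j log h_{r_j}(X^{(j-1)})
                         - sum_j h_0(X^{(j)}) (t_{j+1} - t_j),

so under mass action the per-reaction sufficient statistics are the event
count ``n_r`` and the integrated propensity ``G_r = int h_r(X(t)) / theta_r dt``
(``G_r`` does not depend on ``theta_r``), and the score is

    d log L / d theta_r = E[n_r] / theta_r - E[G_r],

with the expectation over latent paths conditioned on the observations.
The sample mean over RJMCMC draws estimates it; the exact truncated-CME
matrix-exponential transition probability serves as an independent oracle
on small systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .model_core import ReactionNetwork, as_state
from .simulate import ReactionPath

__all__ = [
    "SufficientStats",
    "sufficient_stats",
    "estimate_gradient",
    "cme_oracle",
    "transition_probability",
    "truncated_generator",
]


@dataclass
class SufficientStats:
    """Per-reaction event counts ``n`` and integrated propensities ``G``."""

    n: np.ndarray
    G: np.ndarray

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(n=self.n + other.n, G=self.G + other.G)

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        """Complete-data score of this path at ``theta`` (mass action)."""
        return self.n / theta - self.G


def _path_stats(network: ReactionNetwork, theta: np.ndarray, path: ReactionPath) -> SufficientStats:
    states = path.states(network.A)
    D = network.dhazard_dtheta(states, theta)  # h_r/theta_r for mass action
    edges = np.concatenate(([path.t0], path.times, [path.t1]))
    dt = np.diff(edges)
    G = (D * dt[:, None]).sum(axis=0)
    n = path.counts(network.n_reactions)
    return SufficientStats(n=n, G=G)


def sufficient_stats(network: ReactionNetwork, theta, sample) -> SufficientStats:
    """Sufficient statistics of a :class:`ReactionPath`, a latent-state sample
    (anything with a ``.paths`` attribute), or an iterable of paths.

    Additive over intervals.
    """
    theta = np.asarray(theta, dtype=float)
    if isinstance(sample, ReactionPath):
        return _path_stats(network, theta, sample)
    paths = sample.paths if hasattr(sample, "paths") else list(sample)
    total = SufficientStats(
        n=np.zeros(network.n_reactions, dtype=np.int64), G=np.zeros(network.n_reactions)
    )
    for p in paths:
        total = total + _path_stats(network, theta, p)
    return total


def estimate_gradient(
    network: ReactionNetwork, theta, samples: Iterable
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the log-likelihood gradient and its standard error.

    ``samples`` is a stream of latent-path samples (or SufficientStats).
    Standard errors are the naive standard error of the mean; MCMC
    autocorrelation makes them optimistic unless the caller corrects for
    effective sample size.
    """
    theta = np.asarray(theta, dtype=float)
    scores = []
    for s in samples:
        st = s if isinstance(s, SufficientStats) else sufficient_stats(network, theta, s)
        scores.append(st.gradient(theta))
    if not scores:
        raise ValueError("need at least one post-burn-in sample")
    S = np.asarray(scores)
    grad = S.mean(axis=0)
    se = S.std(axis=0, ddof=1) / np.sqrt(len(S)) if len(S) > 1 else np.zeros_like(grad)
    return grad, se


def gradient_from_arrays(theta: np.ndarray, N: np.ndarray, G: np.ndarray):
    """Fast path used by the SGD driver: per-sample count/propensity arrays."""
    S = N / theta[None, :] - G
    grad = S.mean(axis=0)
    se = S.std(axis=0, ddof=1) / np.sqrt(S.shape[0]) if S.shape[0] > 1 else np.zeros_like(grad)
    return grad, se


# ---------------------------------------------------------------------------
# truncated-CME oracle (validation on small systems)
# ---------------------------------------------------------------------------

def truncated_generator(
    network: ReactionNetwork, theta, bounds
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Rate matrix of the jump process on the box ``prod_a [lo_a, hi_a]``.

    Probability flowing outside the box is lost (absorbing truncation), so
    rows sum to <= 0 with equality away from the boundary.  Returns the
    sparse generator and the (n_states, K) array of enumerated states.
    """
    theta = np.asarray(theta, dtype=float)
    lo = np.array([b[0] for b in bounds], dtype=np.int64)
    hi = np.array([b[1] for b in bounds], dtype=np.int64)
    shape = tuple((hi - lo + 1).tolist())
    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    states = np.stack([g.ravel() for g in grids], axis=1)
    n = states.shape[0]
    H = network.hazard_matrix(states, theta)  # (n, M)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for r in range(network.n_reactions):
        h = H[:, r]
        active = h > 0
        diag -= np.where(active, h, 0.0)
        dest = states + network.A[r]
        inside = active & ((dest >= lo) & (dest <= hi)).all(axis=1)
        if inside.any():
            idx_from = np.nonzero(inside)[0]
            idx_to = np.ravel_multi_index((dest[inside] - lo).T, shape)
            rows.append(idx_from)
            cols.append(idx_to)
            vals.append(h[inside])
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    Q = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return Q, states


def _state_index(x, bounds) -> int:
    lo = np.array([b[0] for b in bounds], dtype=np.int64)
    hi = np.array([b[1] for b in bounds], dtype=np.int64)
    shape = tuple((hi - lo + 1).tolist())
    return int(np.ravel_multi_index(tuple(np.asarray(x) - lo), shape))


def transition_probability(
    network: ReactionNetwork,
    theta,
    x_start,
    tau: float,
    bounds,
    x_end=None,
    mass_tol: float = 1e-8,
):
    """Exact-to-truncation transition distribution (or single probability).

    Propagates the point mass at ``x_start`` through ``expm(Q^T tau)`` and
    checks that the probability lost to the truncation boundary is below
    ``mass_tol``.  With ``x_end`` given, returns ``P(x_end | x_start)``;
    otherwise the full distribution over the box.
    """
    Q, _ = truncated_generator(network, theta, bounds)
    n = Q.shape[0]
    p0 = np.zeros(n)
    p0[_state_index(as_state(x_start), bounds)] = 1.0
    p = expm_multiply(Q.T * tau, p0)
    lost = 1.0 - p.sum()
    if lost > mass_tol:
        raise ValueError(
            f"truncation bounds too tight: {lost:.2e} probability mass left the box"
        )
    if x_end is None:
        return p
    return float(p[_state_index(as_state(x_end), bounds)])


def cme_oracle(
    network: ReactionNetwork,
    theta,
    x_start,
    x_end,
    tau: float,
    bounds,
    rel_step: float = 1e-4,
    mass_tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Exact log transition probability and central-finite-difference gradient.

    Validation-only: cost grows with the truncated state space, so this is
    for small systems and tests.
    """
    theta = np.asarray(theta, dtype=float)
    logp = np.log(
        transition_probability(network, theta, x_start, tau, bounds, x_end, mass_tol)
    )
    grad = np.zeros_like(theta)
    for r in range(len(theta)):
        d = rel_step * theta[r]
        up, dn = theta.copy(), theta.copy()
        up[r] += d
        dn[r] -= d
        pu = transition_probability(network, up, x_start, tau, bounds, x_end, mass_tol)
        pd = transition_probability(network, dn, x_start, tau, bounds, x_end, mass_tol)
        grad[r] = (np.log(pu) - np.log(pd)) / (2 * d)
    return float(logp), grad
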