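"""Elementary modes, null sets, and initial latent paths.

An *elementary mode* for an observed-species subset Γ is a non-zero
non-negative integer vector ``q`` over reactions with ``Ã^T q = 0``, where
``Ã`` keeps only the observed columns of the net-effect matrix: firing the
multiset ``q`` leaves every observed count unchanged.  The *null set* is
the collection of independent (support-minimal, componentwise-minimal)
elementary modes; it is the move alphabet of the reversible-jump sampler.

Initial latent paths are built per interval by integer programming on the
per-reaction counts followed by an ordering repair search that enforces
non-negativity of every intermediate state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model_core import ReactionNetwork
from .simulate import ReactionPath

__all__ = [
    "ElementaryMode",
    "NullSet",
    "NullSetError",
    "InfeasibleIntervalError",
    "compute_null_set",
    "find_reaction_counts",
    "construct_initial_path",
]


class NullSetError(RuntimeError):
    """The observed-species restriction admits no elementary mode."""


class InfeasibleIntervalError(RuntimeError):
    """No reaction-count vector reproduces the observed interval change."""


@dataclass(frozen=True)
class ElementaryMode:
    q: np.ndarray

    @property
    def Q(self) -> int:
        return int(self.q.sum())

    def __str__(self) -> str:
        return "+".join(f"{c}x{j}" for j, c in enumerate(self.q) if c)


@dataclass(frozen=True)
class NullSet:
    modes: tuple[ElementaryMode, ...]
    observed: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.modes)

    def as_matrix(self) -> np.ndarray:
        return np.stack([m.q for m in self.modes])

    def describe(self, network: ReactionNetwork) -> list[str]:
        out = []
        for m in self.modes:
            parts = []
            for j, c in enumerate(m.q):
                if c:
                    name = network.reaction_names[j]
                    parts.append(name if c == 1 else f"{c}*{name}")
            out.append(" + ".join(parts))
        return out


def _enumerate_solutions(A_obs: np.ndarray, cap: int) -> np.ndarray:
    """All non-zero q in {0..cap}^M with A_obs^T q = 0 (bounded exhaustion)."""
    M = A_obs.shape[0]
    grids = np.meshgrid(*([np.arange(cap + 1)] * M), indexing="ij")
    Q = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    Q = Q[Q.any(axis=1)]
    ok = (Q @ A_obs == 0).all(axis=1)
    return Q[ok]


def compute_null_set(
    network: ReactionNetwork,
    observed=None,
    cap: int = 4,
) -> NullSet:
    """Enumerate the null set for the observed subset Γ.

    ``observed`` may be species names or indices; ``None`` means fully
    observed.  Enumeration is exhaustive over coefficients ``0..cap``
    (networks in scope are small), and a candidate is kept only if no other
    solution is componentwise smaller or has strictly smaller support.
    Modes are returned in a deterministic lexicographic order.
    """
    if observed is None:
        obs_idx = tuple(range(network.n_species))
    else:
        obs_idx = tuple(
            network.species_index(s) if isinstance(s, str) else int(s) for s in observed
        )
    if not obs_idx:
        raise ValueError("observed subset must be non-empty")
    A_obs = network.restricted_net_effects(obs_idx)
    sols = _enumerate_solutions(A_obs, cap)
    if len(sols) == 0:
        raise NullSetError(
            "no elementary mode with coefficients <= "
            f"{cap}: reversible-jump moves do not exist for this observed subset"
        )
    supports = sols > 0
    keep = []
    for i in range(len(sols)):
        q = sols[i]
        dominated = False
        for j in range(len(sols)):
            if i == j:
                continue
            p = sols[j]
            if (p <= q).all():
                dominated = True  # componentwise-smaller solution exists
            elif (supports[j] <= supports[i]).all() and not (supports[j] == supports[i]).all():
                dominated = True  # strictly smaller support
            if dominated:
                break
        if not dominated:
            keep.append(tuple(int(c) for c in q))
    keep = sorted(set(keep))
    modes = tuple(ElementaryMode(q=np.array(k, dtype=np.int64)) for k in keep)
    return NullSet(modes=modes, observed=obs_idx)


# ---------------------------------------------------------------------------
# integer programming for per-reaction counts
# ---------------------------------------------------------------------------

def _counts_by_milp(A_obs: np.ndarray, delta: np.ndarray, objective: np.ndarray) -> np.ndarray | None:
    from scipy.optimize import Bounds, LinearConstraint, milp

    M = A_obs.shape[0]
    res = milp(
        c=objective,
        constraints=LinearConstraint(A_obs.T, delta, delta),
        integrality=np.ones(M),
        bounds=Bounds(0, np.inf),
    )
    if not res.success:
        return None
    r = np.rint(res.x).astype(np.int64)
    return r


def _counts_by_branch_and_bound(
    A_obs: np.ndarray, delta: np.ndarray, max_total: int = 200
) -> np.ndarray | None:
    """Pure-Python fallback: smallest-total solution by depth-first search.

    Iterative deepening over the total event count with a simple residual
    bound keeps this exact and fast on the small networks in scope.
    """
    M = A_obs.shape[0]
    for total in range(max_total + 1):
        r = np.zeros(M, dtype=np.int64)

        def dfs(j: int, remaining: int, resid: np.ndarray) -> bool:
            if j == M:
                return remaining == 0 and not resid.any()
            # bound: remaining firings must be able to cancel the residual
            if np.abs(resid).max(initial=0) > remaining * max(
                1, int(np.abs(A_obs[j:]).max(initial=0))
            ):
                return False
            for c in range(remaining + 1):
                r[j] = c
                if dfs(j + 1, remaining - c, resid - c * A_obs[j]):
                    return True
            r[j] = 0
            return False

        if dfs(0, total, delta.astype(np.int64).copy()):
            return r.copy()
    return None


def find_reaction_counts(
    network: ReactionNetwork,
    delta_obs,
    observed=None,
    objective=None,
    solver: str = "milp",
    interval_label: str | None = None,
) -> np.ndarray:
    """Smallest non-negative integer ``r`` with ``Ã^T r = delta_obs``.

    The default objective minimizes the total number of events.  The result
    is re-verified by direct matrix multiplication before it is returned.
    """
    if observed is None:
        obs_idx = tuple(range(network.n_species))
    else:
        obs_idx = tuple(
            network.species_index(s) if isinstance(s, str) else int(s) for s in observed
        )
    A_obs = network.restricted_net_effects(obs_idx)
    delta = np.asarray(delta_obs, dtype=np.int64)
    if delta.shape != (len(obs_idx),):
        raise ValueError("delta_obs must have one entry per observed species")
    obj = np.ones(network.n_reactions) if objective is None else np.asarray(objective, dtype=float)
    if solver == "milp":
        r = _counts_by_milp(A_obs, delta, obj)
    elif solver == "branch_and_bound":
        r = _counts_by_branch_and_bound(A_obs, delta)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if r is None:
        where = f" on interval {interval_label}" if interval_label else ""
        raise InfeasibleIntervalError(
            f"observed change {delta.tolist()} is incompatible with the stoichiometry{where}"
        )
    assert (r >= 0).all() and np.array_equal(r @ A_obs, delta), "ILP post-condition failed"
    return r


# ---------------------------------------------------------------------------
# initial path construction
# ---------------------------------------------------------------------------

def _first_violation(x0: np.ndarray, A: np.ndarray, U: np.ndarray, types: np.ndarray):
    """Index of the first event fired without sufficient reactants, or None."""
    x = x0.copy()
    for i, r in enumerate(types):
        if (x < U[r]).any():
            deficient = int(np.nonzero(x < U[r])[0][0])
            return i, deficient
        x += A[r]
    return None


def _repair_order(
    x0: np.ndarray, A: np.ndarray, U: np.ndarray, types: np.ndarray, max_moves: int
) -> np.ndarray | None:
    """Local swap repair: push each violating event past the earliest later
    event that replenishes the deficient species."""
    seq = list(types)
    for _ in range(max_moves):
        hit = _first_violation(x0, A, U, np.array(seq, dtype=np.int64))
        if hit is None:
            return np.array(seq, dtype=np.int64)
        i, a = hit
        target = None
        for j in range(i + 1, len(seq)):
            if A[seq[j], a] > 0:
                target = j
                break
        if target is None:
            return None  # no later event replenishes: ordering cannot be fixed
        ev = seq.pop(i)
        seq.insert(target, ev)  # after the replenishing event (it shifted left by one)
    return None


def construct_initial_path(
    network: ReactionNetwork,
    x_start,
    r,
    interval: tuple[float, float],
    *,
    rng: np.random.Generator | None = None,
    nullset: NullSet | None = None,
    max_reorder_moves: int = 200,
    max_shuffles: int = 25,
    max_mode_adds: int = 20,
) -> ReactionPath:
    """A valid :class:`ReactionPath` whose per-type counts equal ``r``.

    Event times are i.i.d. uniform on the interval (then sorted); the type
    ordering is found by shuffle + local repair.  If no ordering of ``r`` is
    feasible, one elementary mode at a time is added (the counts remain
    consistent with the endpoints) up to ``max_mode_adds`` before giving up.
    """
    if rng is None:
        rng = np.random.default_rng()
    t0, t1 = float(interval[0]), float(interval[1])
    x0 = np.asarray(x_start, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64).copy()
    A, U = network.A, network.U

    candidates = [r.copy()]
    if nullset is not None and len(nullset):
        extra = r.copy()
        for k in range(max_mode_adds):
            extra = extra + nullset.modes[k % len(nullset)].q
            candidates.append(extra.copy())

    for counts in candidates:
        base = np.repeat(np.arange(network.n_reactions), counts)
        if base.size == 0:
            return ReactionPath(t0=t0, t1=t1, x0=x0, types=base, times=np.array([]))
        for _ in range(max_shuffles):
            types = rng.permutation(base)
            fixed = _repair_order(x0, A, U, types, max_reorder_moves)
            if fixed is not None:
                times = np.sort(rng.uniform(t0, t1, size=len(fixed)))
                # ties among float draws are vanishingly rare; resample if hit
                while len(times) > 1 and not (np.diff(times) > 0).all():
                    times = np.sort(rng.uniform(t0, t1, size=len(fixed)))
                path = ReactionPath(t0=t0, t1=t1, x0=x0, types=fixed, times=times)
                path.validate(network)
                return path
    raise InfeasibleIntervalError(
        f"no valid event ordering found for counts {r.tolist()} on [{t0}, {t1}]"
    )
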