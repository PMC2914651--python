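"""Reversible-jump MCMC over latent reaction paths.

Between two observations the latent data is the full reaction path
``Xi = {(r_j, t_j)}``.  Conditioned on the endpoints, paths with different
event counts live in spaces of different dimension; the sampler jumps
between them with three moves built from the elementary modes of the
observed-species null space:

1. *add* one whole elementary mode ``q`` (probability ``alpha1``), its
   ``Q = sum_j q_j`` new events at i.i.d. uniform times in the interval;
2. *delete* one uniformly chosen combination of existing events matching
   ``q``'s type counts (probability ``alpha2``);
3. *shuffle*: redraw all event times i.i.d. uniform, keeping the multiset
   of types (remaining probability).

With ``r_j`` the per-type event counts of the current path, detailed
balance for the add move gives

    AR_1 = pi(Xi')/pi(Xi) * (alpha2/alpha1) * tau^Q
           / prod_j [ q_j! * C(r_j + q_j, q_j) ]

(the forward density of the new order statistics is prod_j q_j!/tau^{q_j};
the reverse deletes one of prod_j C(r_j+q_j, q_j) combinations); the delete
move is the exact reciprocal, and the shuffle is symmetric, AR_3 =
pi(Xi')/pi(Xi).  A proposal that would fire a reaction without sufficient
reactants, or drive a type count negative, has likelihood zero and is
rejected outright.

Fully observed data make the intervals conditionally independent (one
chain per interval).  With hidden species, a mode that changes the hidden
state at the interior endpoint is paired with the complementary move on
the next interval, which restores the state at the end of the pair; an
extra step shifts the hidden state at the first observation time while
keeping the end of the first interval fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model_core import ReactionNetwork
from .pathspace import NullSet, compute_null_set, construct_initial_path, find_reaction_counts
from .simulate import ObservationSet, ReactionPath

__all__ = [
    "MCMCConfig",
    "LatentState",
    "Move",
    "path_log_likelihood",
    "propose_move",
    "log_acceptance_ratio",
    "sample_paths_full",
    "sample_paths_partial",
    "FullObservedSampler",
    "PartialObservedSampler",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class MCMCConfig:
    """Proposal mix and sample sizes for the path sampler."""

    alpha1: float = 0.25
    alpha2: float = 0.25
    n_samples: int = 1000
    burn_in: int = 100
    thinning: int = 1
    seed: int | None = None
    hidden_cap: int = 10  # cap for uniform hidden-state initialization

    def __post_init__(self):
        if not (self.alpha1 > 0 and self.alpha2 > 0 and self.alpha1 + self.alpha2 < 1):
            raise ValueError("need alpha1, alpha2 > 0 and alpha1 + alpha2 < 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class LatentState:
    """One sampler draw: per-interval paths plus imputed full states."""

    paths: list[ReactionPath]
    obs_states: np.ndarray  # (m, K) full states at the observation times

    def total_reactions(self) -> int:
        return int(sum(p.n_events for p in self.paths))


@dataclass
class Move:
    """A proposal on one interval: new event arrays plus the Hastings term."""

    kind: int  # 1 add, 2 delete, 3 shuffle
    mode: np.ndarray | None
    types: np.ndarray | None
    times: np.ndarray | None
    log_hastings: float
    valid: bool


# ---------------------------------------------------------------------------
# path evaluation
# ---------------------------------------------------------------------------

def _eval_path(network, theta, x0, types, times, t0, t1):
    """Complete-data log-likelihood and integrated propensities.

    Returns ``(loglik, G)``; ``loglik`` is -inf (and G is None) when any
    fired reaction has non-positive hazard at its firing state, which also
    covers every negative-count violation.  Mass-action networks go through
    the compiled single-pass evaluator.
    """
    pack = network._kernel_pack()
    if pack is not None:
        from ._kernels import mass_action_path_eval

        ll, G = mass_action_path_eval(
            *pack,
            np.ascontiguousarray(theta),
            np.ascontiguousarray(x0, dtype=np.int64),
            np.ascontiguousarray(types, dtype=np.int64),
            np.ascontiguousarray(times, dtype=np.float64),
            float(t0),
            float(t1),
        )
        return (ll, G) if ll > NEG_INF else (NEG_INF, None)
    J = len(types)
    K = len(x0)
    states = np.empty((J + 1, K), dtype=np.int64)
    states[0] = x0
    if J:
        np.cumsum(network.A[types], axis=0, out=states[1:])
        states[1:] += x0
    H = network.hazard_matrix(states, theta)
    if J:
        fired = H[np.arange(J), types]
        if (fired <= 0.0).any():
            return NEG_INF, None
        logf = float(np.log(fired).sum())
    else:
        logf = 0.0
    edges = np.empty(J + 2)
    edges[0], edges[-1] = t0, t1
    edges[1:-1] = times
    dt = np.diff(edges)
    total = float((H.sum(axis=1) * dt).sum())
    if network._custom_funcs():
        D = network.dhazard_dtheta(states, theta)
        G = (D * dt[:, None]).sum(axis=0)
    else:
        G = (H * dt[:, None]).sum(axis=0) / theta
    return logf - total, G


def path_log_likelihood(network: ReactionNetwork, theta, path: ReactionPath) -> float:
    """log pi(Xi | theta) for one interval; -inf encodes an invalid path."""
    theta = np.asarray(theta, dtype=float)
    ll, _ = _eval_path(network, theta, path.x0, path.types, path.times, path.t0, path.t1)
    return ll


def _log_choose(n: np.ndarray, k: np.ndarray) -> float:
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)).sum())


class _Interval:
    __slots__ = ("x0", "t0", "t1", "types", "times", "counts", "loglik", "G")

    def __init__(self, network, theta, x0, t0, t1, types, times):
        self.x0 = np.asarray(x0, dtype=np.int64)
        self.t0, self.t1 = float(t0), float(t1)
        self.types = np.asarray(types, dtype=np.int64)
        self.times = np.asarray(times, dtype=float)
        self.counts = np.bincount(self.types, minlength=network.n_reactions)
        self.refresh(network, theta)

    @property
    def tau(self) -> float:
        return self.t1 - self.t0

    def refresh(self, network, theta):
        self.loglik, self.G = _eval_path(
            network, theta, self.x0, self.types, self.times, self.t0, self.t1
        )

    def as_path(self) -> ReactionPath:
        return ReactionPath(
            t0=self.t0, t1=self.t1, x0=self.x0.copy(), types=self.types.copy(), times=self.times.copy()
        )

    def end_state(self, A) -> np.ndarray:
        if len(self.types) == 0:
            return self.x0.copy()
        return self.x0 + A[self.types].sum(axis=0)


def _build_move(interval: _Interval, q, kind: int, rng, la_add, la_del) -> Move:
    """Assemble the proposal arrays and log Hastings correction for a move."""
    tau = interval.tau
    if kind == 3:
        J = len(interval.types)
        if J == 0:
            return Move(3, None, interval.types.copy(), interval.times.copy(), 0.0, True)
        perm = rng.permutation(J)
        times = np.sort(rng.uniform(interval.t0, interval.t1, J))
        return Move(3, None, interval.types[perm], times, 0.0, True)
    Q = int(q.sum())
    r = interval.counts
    if kind == 1:
        new_types = np.concatenate([interval.types, np.repeat(np.arange(len(q)), q)])
        new_times = np.concatenate([interval.times, rng.uniform(interval.t0, interval.t1, Q)])
        order = np.argsort(new_times, kind="stable")
        lpc = (
            (la_del - la_add)
            + Q * math.log(tau)
            - float(gammaln(q + 1).sum())
            - _log_choose(r + q, q)
        )
        return Move(1, q, new_types[order], new_times[order], lpc, True)
    # kind == 2: delete one combination matching q
    if (r < q).any():
        return Move(2, q, None, None, NEG_INF, False)
    drop = []
    for j in np.nonzero(q)[0]:
        idx = np.nonzero(interval.types == j)[0]
        drop.append(rng.choice(idx, size=int(q[j]), replace=False))
    mask = np.ones(len(interval.types), dtype=bool)
    mask[np.concatenate(drop)] = False
    lpc = (
        (la_add - la_del)
        - Q * math.log(tau)
        + float(gammaln(q + 1).sum())
        + _log_choose(r, q)
    )
    return Move(2, q, interval.types[mask], interval.times[mask], lpc, True)


def propose_move(
    network: ReactionNetwork,
    latent,
    interval_index: int,
    nullset: NullSet,
    config: MCMCConfig,
    rng: np.random.Generator,
):
    """One random proposal on the given interval of a latent state.

    Returns ``(proposed_path | None, Move)``; an invalid proposal (type
    count would go negative) carries ``valid=False`` and acceptance 0.
    """
    path = latent.paths[interval_index] if isinstance(latent, LatentState) else latent
    itv = _Interval(network, network.theta, path.x0, path.t0, path.t1, path.types, path.times)
    u = rng.random()
    kind = 1 if u < config.alpha1 else (2 if u < config.alpha1 + config.alpha2 else 3)
    q = nullset.modes[rng.integers(len(nullset))].q
    mv = _build_move(itv, q, kind, rng, math.log(config.alpha1), math.log(config.alpha2))
    if not mv.valid:
        return None, mv
    prop = ReactionPath(t0=itv.t0, t1=itv.t1, x0=itv.x0.copy(), types=mv.types, times=mv.times)
    return prop, mv


def log_acceptance_ratio(
    network: ReactionNetwork,
    theta,
    current: ReactionPath,
    proposed: ReactionPath | None,
    move: Move,
) -> float:
    """log AR of a proposal; -inf for invalid proposals.

    The identity proposal (shuffle reproducing the same times) gives 0.
    """
    if not move.valid or proposed is None:
        return NEG_INF
    cur = path_log_likelihood(network, theta, current)
    prop = path_log_likelihood(network, theta, proposed)
    if prop == NEG_INF:
        return NEG_INF
    return prop - cur + move.log_hastings


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

class _BaseSampler:
    network: ReactionNetwork
    theta: np.ndarray
    config: MCMCConfig
    nullset: NullSet
    intervals: list[_Interval]
    obs_states: np.ndarray

    def __init__(self):
        self.n_proposed = 0
        self.n_accepted = 0
        self.diag_rows: list[tuple] = []
        self._iteration = 0

    # -- shared plumbing ----------------------------------------------------
    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(1, self.n_proposed)

    def update_theta(self, theta) -> None:
        """Re-evaluate all cached path likelihoods at new rate parameters.

        Paths stay valid when theta changes, so chains warm-start across
        gradient-descent iterations.
        """
        self.theta = np.asarray(theta, dtype=float)
        for itv in self.intervals:
            itv.refresh(self.network, self.theta)

    def _accept(self, log_ar: float, rng) -> bool:
        self.n_proposed += 1
        if log_ar >= 0 or math.log(rng.random()) < log_ar:
            self.n_accepted += 1
            return True
        return False

    def total_reactions(self) -> int:
        return int(sum(len(itv.types) for itv in self.intervals))

    def snapshot(self) -> LatentState:
        return LatentState(
            paths=[itv.as_path() for itv in self.intervals], obs_states=self.obs_states.copy()
        )

    def stats_arrays(self):
        """Per-interval sums of event counts and integrated propensities."""
        N = np.zeros(self.network.n_reactions, dtype=np.int64)
        G = np.zeros(self.network.n_reactions)
        for itv in self.intervals:
            N += itv.counts
            G += itv.G
        return N, G

    def run(self, n_samples: int | None = None, burn_in: int | None = None):
        """Burn in, then collect per-sweep sufficient-statistic arrays.

        Returns ``(N, G)`` with one row per retained sweep.
        """
        cfg = self.config
        n_samples = cfg.n_samples if n_samples is None else n_samples
        burn_in = cfg.burn_in if burn_in is None else burn_in
        for _ in range(burn_in):
            self.sweep()
        rows_n = np.empty((n_samples, self.network.n_reactions))
        rows_g = np.empty((n_samples, self.network.n_reactions))
        kept = 0
        while kept < n_samples:
            self.sweep()
            if self._iteration % cfg.thinning == 0:
                N, G = self.stats_arrays()
                rows_n[kept] = N
                rows_g[kept] = G
                kept += 1
        return rows_n, rows_g

    def samples(self, n_samples: int | None = None, burn_in: int | None = None):
        """Generator of post-burn-in :class:`LatentState` snapshots."""
        cfg = self.config
        n_samples = cfg.n_samples if n_samples is None else n_samples
        burn_in = cfg.burn_in if burn_in is None else burn_in
        for _ in range(burn_in):
            self.sweep()
        kept = 0
        while kept < n_samples:
            self.sweep()
            if self._iteration % cfg.thinning == 0:
                yield self.snapshot()
                kept += 1

    def diagnostics(self):
        import pandas as pd

        return pd.DataFrame(
            self.diag_rows, columns=["iteration", "interval", "total_reactions", "accepted", "move_type"]
        )

    def sweep(self):  # pragma: no cover - overridden
        raise NotImplementedError


class FullObservedSampler(_BaseSampler):
    """Independent per-interval chains conditioned on full-state endpoints."""

    def __init__(
        self,
        network: ReactionNetwork,
        theta,
        observations: ObservationSet,
        config: MCMCConfig | None = None,
        nullset: NullSet | None = None,
        rng: np.random.Generator | None = None,
        record_detail: bool = False,
    ):
        super().__init__()
        self.network = network
        self.theta = np.asarray(theta, dtype=float)
        self.config = config or MCMCConfig()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        if not observations.is_full(network):
            raise ValueError("FullObservedSampler needs every species observed")
        self.record_detail = record_detail
        obs_idx = observations.observed_indices(network)
        order = np.argsort(obs_idx)
        # reorder observation columns into network species order
        self.obs_states = observations.counts[:, order].astype(np.int64)
        self.obs_times = observations.times
        self.nullset = nullset or compute_null_set(network, None)
        self._la1 = math.log(self.config.alpha1)
        self._la2 = math.log(self.config.alpha2)
        self.intervals = []
        for s in range(len(self.obs_times) - 1):
            delta = self.obs_states[s + 1] - self.obs_states[s]
            r = find_reaction_counts(network, delta, interval_label=str(s))
            path = construct_initial_path(
                network,
                self.obs_states[s],
                r,
                (self.obs_times[s], self.obs_times[s + 1]),
                rng=self.rng,
                nullset=self.nullset,
            )
            itv = _Interval(network, self.theta, path.x0, path.t0, path.t1, path.types, path.times)
            if itv.loglik == NEG_INF:
                raise RuntimeError(f"initial path on interval {s} has zero likelihood")
            self.intervals.append(itv)

    def sweep(self):
        rng = self.rng
        cfg = self.config
        modes = self.nullset.modes
        for i, itv in enumerate(self.intervals):
            u = rng.random()
            kind = 1 if u < cfg.alpha1 else (2 if u < cfg.alpha1 + cfg.alpha2 else 3)
            q = modes[rng.integers(len(modes))].q
            mv = _build_move(itv, q, kind, rng, self._la1, self._la2)
            accepted = False
            if mv.valid:
                ll, G = _eval_path(
                    self.network, self.theta, itv.x0, mv.types, mv.times, itv.t0, itv.t1
                )
                if ll > NEG_INF and self._accept(ll - itv.loglik + mv.log_hastings, rng):
                    itv.types, itv.times, itv.loglik, itv.G = mv.types, mv.times, ll, G
                    itv.counts = np.bincount(mv.types, minlength=self.network.n_reactions)
                    accepted = True
                elif ll == NEG_INF:
                    self.n_proposed += 1
            else:
                self.n_proposed += 1
            if self.record_detail:
                self.diag_rows.append((self._iteration, i, len(itv.types), accepted, mv.kind))
        self._iteration += 1
        if not self.record_detail:
            self.diag_rows.append((self._iteration, -1, self.total_reactions(), self.n_accepted, 0))


class PartialObservedSampler(_BaseSampler):
    """Correlated pair updates for hidden species (complementary moves)."""

    def __init__(
        self,
        network: ReactionNetwork,
        theta,
        observations: ObservationSet,
        config: MCMCConfig | None = None,
        nullset: NullSet | None = None,
        rng: np.random.Generator | None = None,
        max_init_retries: int = 50,
        n_init_candidates: int = 8,
        record_detail: bool = False,
    ):
        super().__init__()
        self.network = network
        self.theta = np.asarray(theta, dtype=float)
        self.config = config or MCMCConfig()
        self.rng = rng if rng is not None else np.random.default_rng(self.config.seed)
        self.record_detail = record_detail
        self.obs_idx = observations.observed_indices(network)
        self.hidden_idx = tuple(
            a for a in range(network.n_species) if a not in set(self.obs_idx)
        )
        if not self.hidden_idx:
            raise ValueError("no hidden species: use FullObservedSampler")
        self.obs_times = observations.times
        self.obs_counts = observations.counts.astype(np.int64)
        self.nullset = nullset or compute_null_set(network, self.obs_idx)
        self._la1 = math.log(self.config.alpha1)
        self._la2 = math.log(self.config.alpha2)
        # net state change of each mode (zero on observed components)
        self._mode_delta = [
            np.asarray(network.A.T @ m.q, dtype=np.int64) for m in self.nullset.modes
        ]
        self._conserved = self._conserved_groups(observations)
        # Hidden starts are drawn uniformly, but a draw far from the
        # posterior leaves the chain a long random walk away (the hidden
        # field moves one composite mode at a time).  Score several feasible
        # candidates by their complete-data likelihood at the candidate's
        # own refined rates and keep the best.
        last_err: Exception | None = None
        best = None
        successes = 0
        for _ in range(max_init_retries):
            try:
                intervals, states = self._initialize()
            except Exception as exc:  # infeasible hidden draw: retry
                last_err = exc
                continue
            successes += 1
            n = np.zeros(network.n_reactions)
            g = np.zeros(network.n_reactions)
            for itv in intervals:
                n += itv.counts
                g += itv.G
            theta_ref = np.clip((n + 0.5) / np.maximum(g, 1e-12), 1e-4, 50.0)
            score = sum(
                _eval_path(network, theta_ref, itv.x0, itv.types, itv.times, itv.t0, itv.t1)[0]
                for itv in intervals
            )
            if best is None or score > best[0]:
                best = (score, intervals, states)
            if successes >= n_init_candidates:
                break
        if best is None:
            raise RuntimeError(
                f"could not build an initial latent state after {max_init_retries} tries"
            ) from last_err
        _, self.intervals, self.obs_states = best

    def _conserved_groups(self, observations: ObservationSet):
        groups = list(self.network.conserved)
        name_to_idx = {s: i for i, s in enumerate(self.network.species_names)}
        for names, total in observations.conserved_totals:
            idx = tuple(name_to_idx[s] for s in names)
            if not any(set(idx) == set(g[0]) for g in groups):
                groups.append((idx, total))
        return groups

    def _draw_hidden_start(self) -> np.ndarray:
        """Uniform hidden components at t_1, honoring known conserved totals."""
        rng = self.rng
        K = self.network.n_species
        x = np.zeros(K, dtype=np.int64)
        x[list(self.obs_idx)] = self.obs_counts[0]
        assigned = set()
        for idx, total in self._conserved:
            hidden_members = [a for a in idx if a in set(self.hidden_idx)]
            remaining = total - int(sum(x[a] for a in idx if a not in set(self.hidden_idx)))
            if remaining < 0:
                raise RuntimeError("observations violate a declared conserved total")
            if not hidden_members:
                continue
            # uniform composition of `remaining` over the hidden members
            cuts = np.sort(rng.integers(0, remaining + 1, size=len(hidden_members) - 1))
            parts = np.diff(np.concatenate(([0], cuts, [remaining])))
            for a, c in zip(hidden_members, parts):
                x[a] = c
                assigned.add(a)
        cap = self.config.hidden_cap
        for a in self.hidden_idx:
            if a not in assigned:
                x[a] = rng.integers(0, cap + 1)
        return x

    def _initialize(self):
        network = self.network
        x = self._draw_hidden_start()
        states = [x.copy()]
        intervals = []
        # prefer explanations that leave hidden species alone: per-interval
        # minimal counts chosen independently would otherwise drain finite
        # hidden stocks (e.g. bound promoters) across the window
        hidden = list(self.hidden_idx)
        objective = 1.0 + np.abs(network.A[:, hidden]).sum(axis=1)
        for s in range(len(self.obs_times) - 1):
            delta = self.obs_counts[s + 1] - self.obs_counts[s]
            r = find_reaction_counts(
                network, delta, observed=self.obs_idx, objective=objective,
                interval_label=str(s),
            )
            path = construct_initial_path(
                network,
                states[-1],
                r,
                (self.obs_times[s], self.obs_times[s + 1]),
                rng=self.rng,
                nullset=self.nullset,
            )
            itv = _Interval(network, self.theta, path.x0, path.t0, path.t1, path.types, path.times)
            if itv.loglik == NEG_INF:
                raise RuntimeError(f"initial path on interval {s} has zero likelihood")
            intervals.append(itv)
            states.append(itv.end_state(network.A))
        return intervals, np.stack(states)

    # -- moves --------------------------------------------------------------
    def _try_single(self, i: int, mv: Move, shift_end: np.ndarray | None, rng) -> bool:
        itv = self.intervals[i]
        ll, G = _eval_path(self.network, self.theta, itv.x0, mv.types, mv.times, itv.t0, itv.t1)
        if ll == NEG_INF:
            self.n_proposed += 1
            return False
        if self._accept(ll - itv.loglik + mv.log_hastings, rng):
            itv.types, itv.times, itv.loglik, itv.G = mv.types, mv.times, ll, G
            itv.counts = np.bincount(mv.types, minlength=self.network.n_reactions)
            if shift_end is not None:
                self.obs_states[i + 1] += shift_end
            return True
        return False

    def _pair_update(self, i: int, rng) -> bool:
        cfg = self.config
        k = rng.integers(len(self.nullset))
        q = self.nullset.modes[k].q
        d = self._mode_delta[k]
        u = rng.random()
        kind = 1 if u < cfg.alpha1 else (2 if u < cfg.alpha1 + cfg.alpha2 else 3)
        itv = self.intervals[i]
        mv = _build_move(itv, q, kind, rng, self._la1, self._la2)
        if not mv.valid:
            self.n_proposed += 1
            return False
        if kind == 3 or not d.any():
            return self._try_single(i, mv, None, rng)
        shift = d if kind == 1 else -d
        if i == len(self.intervals) - 1:
            # last interval: the hidden state at t_m is free to move
            return self._try_single(i, mv, shift, rng)
        # complementary move on interval i+1 with the shifted start state;
        # it is forced (not chosen), so no alpha ratio enters its Hastings term
        nxt = self.intervals[i + 1]
        comp_kind = 2 if kind == 1 else 1
        comp = _build_move(nxt, q, comp_kind, rng, 0.0, 0.0)
        if not comp.valid:
            self.n_proposed += 1
            return False
        ll_i, G_i = _eval_path(self.network, self.theta, itv.x0, mv.types, mv.times, itv.t0, itv.t1)
        if ll_i == NEG_INF:
            self.n_proposed += 1
            return False
        new_x0 = nxt.x0 + shift
        ll_n, G_n = _eval_path(
            self.network, self.theta, new_x0, comp.types, comp.times, nxt.t0, nxt.t1
        )
        if ll_n == NEG_INF:
            self.n_proposed += 1
            return False
        log_ar = (ll_i - itv.loglik + mv.log_hastings) + (ll_n - nxt.loglik + comp.log_hastings)
        if self._accept(log_ar, rng):
            itv.types, itv.times, itv.loglik, itv.G = mv.types, mv.times, ll_i, G_i
            itv.counts = np.bincount(mv.types, minlength=self.network.n_reactions)
            nxt.x0 = new_x0
            nxt.types, nxt.times, nxt.loglik, nxt.G = comp.types, comp.times, ll_n, G_n
            nxt.counts = np.bincount(comp.types, minlength=self.network.n_reactions)
            self.obs_states[i + 1] += shift
            return True
        return False

    def _start_state_update(self, rng) -> bool:
        """Shift the hidden state at t_1, keeping the end of interval 1 fixed.

        Adding mode q to interval 1 while moving x(t_1) by -A^T q (or the
        delete/+ mirror) leaves the state at t_2 unchanged; the direction is
        chosen with equal probability, so only the path-space Hastings terms
        remain.
        """
        itv = self.intervals[0]
        k = rng.integers(len(self.nullset))
        q = self.nullset.modes[k].q
        d = self._mode_delta[k]
        if not d.any():
            return False  # mode never moves hidden states; nothing to do
        add = rng.random() < 0.5
        la = math.log(0.5)
        mv = _build_move(itv, q, 1 if add else 2, rng, la, la)
        if not mv.valid:
            self.n_proposed += 1
            return False
        new_x0 = itv.x0 - d if add else itv.x0 + d
        if (new_x0 < 0).any():
            self.n_proposed += 1
            return False
        ll, G = _eval_path(self.network, self.theta, new_x0, mv.types, mv.times, itv.t0, itv.t1)
        if ll == NEG_INF:
            self.n_proposed += 1
            return False
        if self._accept(ll - itv.loglik + mv.log_hastings, rng):
            itv.x0 = new_x0
            itv.types, itv.times, itv.loglik, itv.G = mv.types, mv.times, ll, G
            itv.counts = np.bincount(mv.types, minlength=self.network.n_reactions)
            self.obs_states[0] = new_x0
            return True
        return False

    def _level_shift_update(self, rng) -> bool:
        """Shift the entire hidden trajectory by one mode's net effect.

        Adding ``d = +-A^T q`` to the start state while keeping every event
        translates all states at all times by ``d`` (observed components are
        zero by the mode property).  The proposal is symmetric, so the
        acceptance is the plain likelihood ratio over all intervals.  This
        targets the slowest mode of the hidden field -- its overall level --
        which local pair moves only change one time point per sweep.
        """
        k = rng.integers(len(self.nullset))
        d = self._mode_delta[k]
        if not d.any():
            return False
        if rng.random() < 0.5:
            d = -d
        if (self.obs_states + d < 0).any():
            self.n_proposed += 1
            return False
        log_ar = 0.0
        evals = []
        for itv in self.intervals:
            ll, G = _eval_path(
                self.network, self.theta, itv.x0 + d, itv.types, itv.times, itv.t0, itv.t1
            )
            if ll == NEG_INF:
                self.n_proposed += 1
                return False
            evals.append((ll, G))
            log_ar += ll - itv.loglik
        if self._accept(log_ar, rng):
            for itv, (ll, G) in zip(self.intervals, evals):
                itv.x0 = itv.x0 + d
                itv.loglik, itv.G = ll, G
            self.obs_states += d
            return True
        return False

    def sweep(self):
        rng = self.rng
        for i in range(len(self.intervals)):
            accepted = self._pair_update(i, rng)
            if self.record_detail:
                self.diag_rows.append(
                    (self._iteration, i, len(self.intervals[i].types), accepted, 0)
                )
        self._start_state_update(rng)
        self._level_shift_update(rng)
        self._iteration += 1
        if not self.record_detail:
            self.diag_rows.append((self._iteration, -1, self.total_reactions(), self.n_accepted, 0))


def sample_paths_full(
    network: ReactionNetwork, theta, observations: ObservationSet, config: MCMCConfig
):
    """Stream of post-burn-in latent-path samples, fully observed case."""
    sampler = FullObservedSampler(network, theta, observations, config)
    yield from sampler.samples()


def sample_paths_partial(
    network: ReactionNetwork, theta, observations: ObservationSet, config: MCMCConfig
):
    """Stream of post-burn-in latent-path samples, partially observed case."""
    sampler = PartialObservedSampler(network, theta, observations, config)
    yield from sampler.samples()
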