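"""Exact stochastic simulation (Gillespie direct method) and observation extraction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import ReactionNetwork, as_state

__all__ = ["ReactionPath", "ObservationSet", "simulate_ssa", "make_observations", "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass
class ReactionPath:
    """An ordered record of reaction events on one time interval.

    ``types[j]`` is the 0-based reaction index of the j-th event, fired at
    ``times[j]``; times are strictly increasing inside the open interval
    ``(t0, t1)``.  Replaying the events from ``x0`` via the rows of the
    net-effect matrix must keep every count non-negative.
    """

    t0: float
    t1: float
    x0: np.ndarray
    types: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.x0 = as_state(self.x0)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def tau(self) -> float:
        return self.t1 - self.t0

    @property
    def n_events(self) -> int:
        return len(self.types)

    def counts(self, n_reactions: int) -> np.ndarray:
        return np.bincount(self.types, minlength=n_reactions)

    def states(self, A: np.ndarray) -> np.ndarray:
        """All visited states, shape (J+1, K): ``x0`` then post-event states."""
        out = np.empty((self.n_events + 1, A.shape[1]), dtype=np.int64)
        out[0] = self.x0
        if self.n_events:
            out[1:] = self.x0 + np.cumsum(A[self.types], axis=0)
        return out

    def end_state(self, A: np.ndarray) -> np.ndarray:
        if self.n_events == 0:
            return self.x0.copy()
        return self.x0 + A[self.types].sum(axis=0)

    def state_at(self, A: np.ndarray, t: float) -> np.ndarray:
        """State at time ``t`` with events at exactly ``t`` ordered before sampling."""
        j = int(np.searchsorted(self.times, t, side="right"))
        if j == 0:
            return self.x0.copy()
        return self.x0 + A[self.types[:j]].sum(axis=0)

    def validate(self, network: ReactionNetwork) -> None:
        if not self.tau > 0:
            raise ValueError("interval must have positive length")
        if self.n_events:
            if not (np.diff(self.times) > 0).all():
                raise ValueError("event times must be strictly increasing")
            if self.times[0] <= self.t0 or self.times[-1] >= self.t1:
                raise ValueError("event times must lie inside the open interval")
            if self.types.min() < 0 or self.types.max() >= network.n_reactions:
                raise ValueError("event type out of range")
            if self.states(network.A).min() < 0:
                raise ValueError("replay drives a species count negative")


@dataclass
class ObservationSet:
    """Discrete time-course observations of a subset of species.

    ``counts[i, j]`` is the copy number of ``species[j]`` at ``times[i]``.
    ``conserved_totals`` carries known totals (name tuple -> int) that the
    partially observed sampler may rely on (e.g. DNA + DNA.P2).
    """

    times: np.ndarray
    species: tuple[str, ...]
    counts: np.ndarray
    conserved_totals: tuple[tuple[tuple[str, ...], int], ...] = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least two observation times")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("observation times must be strictly increasing")
        if not self.species:
            raise ValueError("observed-species set must be non-empty")
        if self.counts.shape != (len(self.times), len(self.species)):
            raise ValueError("counts must have shape (n_times, n_observed_species)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            r = np.rint(self.counts)
            if not np.allclose(self.counts, r):
                raise ValueError("observed counts must be integers")
            self.counts = r.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("observed counts must be non-negative")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def observed_indices(self, network: ReactionNetwork) -> tuple[int, ...]:
        return tuple(network.species_index(s) for s in self.species)

    def is_full(self, network: ReactionNetwork) -> bool:
        return set(self.species) == set(network.species_names)


def simulate_ssa(
    network: ReactionNetwork,
    x0,
    t_end: float,
    *,
    seed=None,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
    max_events: int = 10_000_000,
) -> ReactionPath:
    """Exact realization of the Markov jump process on ``[t_start, t_end]``.

    Gillespie's direct method: waiting times are exponential in the total
    hazard and the next reaction is chosen proportionally to its hazard.
    Raises :class:`SimulationError` when ``max_events`` is exceeded, which
    guards against hazard explosion.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = as_state(x0, network.n_species).copy()
    t = float(t_start)
    types: list[int] = []
    times: list[float] = []
    M = network.n_reactions
    while True:
        h = network.hazards(x)
        h0 = float(h.sum())
        if h0 <= 0.0:
            break
        t = t + rng.exponential(1.0 / h0)
        if t >= t_end:
            break
        r = int(np.searchsorted(np.cumsum(h), rng.random() * h0))
        r = min(r, M - 1)
        x = x + network.A[r]
        types.append(r)
        times.append(t)
        if len(types) > max_events:
            raise SimulationError(f"more than {max_events} events before t={t_end}: runaway hazards?")
    return ReactionPath(t0=t_start, t1=float(t_end), x0=as_state(x0), types=np.array(types, dtype=np.int64), times=np.array(times))


def make_observations(
    path: ReactionPath,
    network: ReactionNetwork,
    times: Sequence[float],
    observed: Sequence[str] | None = None,
) -> ObservationSet:
    """Record the trajectory state at the given times, restricted to ``observed``.

    Events at exactly an observation time (a probability-zero tie) are
    ordered before the observation, so each row is the left-limit-inclusive
    state at that time.
    """
    times = np.asarray(times, dtype=float)
    if times.min() < path.t0 or times.max() > path.t1:
        raise ValueError("requested observation time outside the simulated horizon")
    if observed is None:
        observed = network.species_names
    obs_idx = [network.species_index(s) for s in observed]
    rows = np.empty((len(times), len(obs_idx)), dtype=np.int64)
    for i, t in enumerate(times):
        rows[i] = path.state_at(network.A, t)[obs_idx]
    conserved = tuple(
        (tuple(network.species_names[i] for i in idx), total) for idx, total in network.conserved
    )
    return ObservationSet(times=times, species=tuple(observed), counts=rows, conserved_totals=conserved)
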