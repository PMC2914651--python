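"""The two benchmark systems and programmatic benchmark-dataset generation.

Birth-death process (one species A)::

    R1: A -> 0    h1 = k1 * nA      (first-order decay)
    R2: 0 -> A    h2 = k2           (zeroth-order production)

Prokaryotic auto-regulatory gene network (five species): protein dimers
repress their own transcription by binding the promoter::

    R1: DNA + P2 -> DNA.P2          repression (binding)
    R2: DNA.P2 -> DNA + P2          unbinding
    R3: DNA -> DNA + mRNA           transcription
    R4: mRNA -> 0                   mRNA degradation
    R5: 2 P -> P2                   dimerization
    R6: P2 -> 2 P                   dissociation
    R7: mRNA -> mRNA + P            translation
    R8: P -> 0                      protein degradation

DNA + DNA.P2 = DNA_t is conserved.  Benchmarks are produced by exact SSA
simulation followed by discrete observation extraction, so every dataset
is regenerated from a seed rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ReactionNetwork, build_network
from .simulate import ObservationSet, ReactionPath, make_observations, simulate_ssa

__all__ = [
    "BIRTH_DEATH_THETA",
    "AUTOREG_THETA",
    "BenchmarkSpec",
    "birth_death_network",
    "autoregulatory_network",
    "generate_benchmark",
]

BIRTH_DEATH_THETA = (0.03, 0.6)
AUTOREG_THETA = (0.1, 0.7, 0.35, 0.3, 0.1, 0.9, 0.2, 0.1)
AUTOREG_SPECIES = ("DNA", "DNA.P2", "mRNA", "P", "P2")


def birth_death_network(k1: float = 0.03, k2: float = 0.6) -> ReactionNetwork:
    """Production/degradation of a single species; net-effect matrix (-1, 1)^T."""
    return build_network(
        {
            "species": ["A"],
            "reactions": [
                {"name": "R1", "reactants": {"A": 1}, "products": {}, "theta": k1},
                {"name": "R2", "reactants": {}, "products": {"A": 1}, "theta": k2},
            ],
        }
    )


def autoregulatory_network(theta=AUTOREG_THETA, dna_total: int = 10) -> ReactionNetwork:
    """Eight-reaction negative-feedback gene circuit with conserved DNA total."""
    k = tuple(float(v) for v in theta)
    if len(k) != 8:
        raise ValueError("the auto-regulatory network takes 8 rate constants")
    return build_network(
        {
            "species": list(AUTOREG_SPECIES),
            "reactions": [
                {"name": "R1", "reactants": {"DNA": 1, "P2": 1}, "products": {"DNA.P2": 1}, "theta": k[0]},
                {"name": "R2", "reactants": {"DNA.P2": 1}, "products": {"DNA": 1, "P2": 1}, "theta": k[1]},
                {"name": "R3", "reactants": {"DNA": 1}, "products": {"DNA": 1, "mRNA": 1}, "theta": k[2]},
                {"name": "R4", "reactants": {"mRNA": 1}, "products": {}, "theta": k[3]},
                {"name": "R5", "reactants": {"P": 2}, "products": {"P2": 1}, "theta": k[4]},
                {"name": "R6", "reactants": {"P2": 1}, "products": {"P": 2}, "theta": k[5]},
                {"name": "R7", "reactants": {"mRNA": 1}, "products": {"mRNA": 1, "P": 1}, "theta": k[6]},
                {"name": "R8", "reactants": {"P": 1}, "products": {}, "theta": k[7]},
            ],
            "conserved": [{"species": ["DNA", "DNA.P2"], "total": int(dna_total)}],
        }
    )


@dataclass(frozen=True)
class BenchmarkSpec:
    """Design of one simulated observation dataset.

    ``m`` observation rows on the arithmetic grid ``0, dt, ..., (m-1) dt``;
    ``observed=None`` means fully observed.  ``x0=None`` selects the model
    default start: the stationary mean ``round(k2/k1)`` for birth-death and
    all DNA unbound, no transcripts or protein, for the gene network.
    """

    model: str = "birth_death"
    theta: tuple = BIRTH_DEATH_THETA
    m: int = 21
    dt: float = 2.0
    dna_total: int = 10
    observed: tuple | None = None
    seed: int | None = None
    x0: tuple | None = None

    def __post_init__(self):
        if self.m < 2 or self.dt <= 0:
            raise ValueError("need m >= 2 and dt > 0")
        if any(v <= 0 for v in self.theta):
            raise ValueError("true rate constants must be positive")

    def network(self) -> ReactionNetwork:
        if self.model == "birth_death":
            return birth_death_network(*self.theta)
        if self.model == "autoreg":
            return autoregulatory_network(self.theta, self.dna_total)
        raise ValueError(f"unknown benchmark model {self.model!r}")

    def start_state(self) -> np.ndarray:
        if self.x0 is not None:
            return np.asarray(self.x0, dtype=np.int64)
        if self.model == "birth_death":
            return np.array([int(round(self.theta[1] / self.theta[0]))], dtype=np.int64)
        return np.array([self.dna_total, 0, 0, 0, 0], dtype=np.int64)


def generate_benchmark(spec: BenchmarkSpec) -> tuple[ObservationSet, ReactionPath]:
    """Simulate the model and extract the observation table.

    Returns the (possibly partially observed) dataset and the ground-truth
    trajectory it was read off from.  Fixed seed => identical dataset.
    """
    network = spec.network()
    times = np.arange(spec.m) * spec.dt
    rng = np.random.default_rng(spec.seed)
    traj = simulate_ssa(network, spec.start_state(), float(times[-1]) + 1e-9, rng=rng)
    obs = make_observations(traj, network, times, spec.observed)
    return obs, traj
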