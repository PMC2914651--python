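"""Reaction networks and hazard (propensity) functions.

A stochastic kinetic model is a continuous-time Markov jump process on
non-negative integer molecule counts.  A network of ``M`` reactions over
``K`` species is written ``U S -> V S`` with non-negative integer
reactant/product stoichiometry matrices ``U`` and ``V`` (both M x K); the
net-effect matrix ``A = V - U`` gives the state change caused by one firing
of each reaction.  Reaction ``r`` fires at hazard ``h_r(X, theta)``; for
mass-action kinetics

    h_r(X) = theta_r * prod_a C(x_a, u_ra)

with the binomial-coefficient combinatorial factor counting distinct
reactant combinations (the alternative falling-factorial convention
``x (x-1) ... (x-u+1)`` is available as a model-level option; the two agree
whenever every ``u_ra <= 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSpecError",
    "ReactionNetwork",
    "as_state",
    "build_network",
    "hazards",
]

CONVENTIONS = ("binomial", "falling_factorial")


class ModelSpecError(ValueError):
    """A model description violates the network invariants."""


def as_state(x, n_species: int | None = None) -> np.ndarray:
    """Validate and convert ``x`` to an integer molecule-count vector."""
    arr = np.asarray(x)
    if arr.ndim != 1:
        raise ValueError("state must be a 1-D vector of counts")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError("molecule counts must be integers")
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("molecule counts must be non-negative")
    if n_species is not None and arr.shape[0] != n_species:
        raise ValueError(f"state has {arr.shape[0]} entries, expected {n_species}")
    return arr


@dataclass(frozen=True)
class ReactionNetwork:
    """A validated reaction network with rate parameters.

    Attributes
    ----------
    species_names : tuple of str
        Unique, non-empty identifiers for the K species.
    U, V : (M, K) int arrays
        Reactant and product stoichiometries.
    A : (M, K) int array
        Net-effect matrix, always exactly ``V - U``.
    theta : (M,) float array
        Strictly positive rate constants, one per reaction.
    rate_laws : tuple of str
        Per-reaction tag, ``"mass_action"`` or a custom arithmetic
        expression over species names and the symbol ``theta``.
    conserved : tuple of (indices, total)
        Known conserved unit-coefficient totals (e.g. DNA + DNA.P2).
    convention : str
        Mass-action combinatorial factor, ``"binomial"`` (default) or
        ``"falling_factorial"``.
    """

    species_names: tuple[str, ...]
    U: np.ndarray
    V: np.ndarray
    A: np.ndarray
    theta: np.ndarray
    rate_laws: tuple[str, ...]
    reaction_names: tuple[str, ...]
    conserved: tuple[tuple[tuple[int, ...], int], ...] = ()
    convention: str = "binomial"
    _custom: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return self.U.shape[0]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def with_theta(self, theta) -> "ReactionNetwork":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_reactions,) or (theta <= 0).any():
            raise ModelSpecError("theta must be positive with one entry per reaction")
        return replace(self, theta=theta)

    # -- hazards -------------------------------------------------------------
    def _reactant_list(self) -> list[list[tuple[int, int]]]:
        out = []
        for r in range(self.n_reactions):
            out.append([(a, int(self.U[r, a])) for a in np.nonzero(self.U[r])[0]])
        return out

    def hazard_matrix(self, states: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """Hazards of every reaction at every row of ``states`` (n, K) -> (n, M).

        Rows may transiently contain negative counts (mid-proposal replay);
        the returned factor is then <= 0 for the affected reaction so that
        callers can detect the invalid firing.
        """
        theta = self.theta if theta is None else theta
        states = np.atleast_2d(states)
        n = states.shape[0]
        H = np.empty((n, self.n_reactions), dtype=float)
        reactants = self._cached_reactants
        for r in range(self.n_reactions):
            law = self.rate_laws[r]
            if law == "mass_action":
                fac = np.ones(n)
                for a, u in reactants[r]:
                    col = states[:, a].astype(float)
                    for i in range(u):
                        fac = fac * (col - i)
                    if self.convention == "binomial" and u > 1:
                        fac = fac / math.factorial(u)
                H[:, r] = theta[r] * fac
            else:
                f = self._custom_funcs()[r][0]
                cols = [states[:, a].astype(float) for a in range(self.n_species)]
                H[:, r] = np.broadcast_to(f(theta[r], *cols), (n,))
        return H

    def hazards(self, x, theta: np.ndarray | None = None) -> np.ndarray:
        """Hazard vector ``h(X, theta)`` at a single valid state."""
        x = as_state(x, self.n_species)
        return self.hazard_matrix(x[None, :], theta)[0]

    # custom rate laws: expression strings compiled lazily via sympy
    def _custom_funcs(self) -> dict[int, tuple[Callable, Callable]]:
        if "funcs" not in self._custom:
            import sympy

            funcs = {}
            syms = sympy.symbols([f"x_{i}" for i in range(self.n_species)])
            th = sympy.Symbol("theta", positive=True)
            local = {name: syms[i] for i, name in enumerate(self.species_names)}
            local["theta"] = th
            for r, law in enumerate(self.rate_laws):
                if law == "mass_action":
                    continue
                expr = sympy.sympify(law, locals=local)
                f = sympy.lambdify((th, *syms), expr, modules="numpy")
                df = sympy.lambdify((th, *syms), sympy.diff(expr, th), modules="numpy")
                funcs[r] = (f, df)
            self._custom["funcs"] = funcs
        return self._custom["funcs"]

    def dhazard_dtheta(self, states: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """Per-reaction ``dh_r/dtheta_r`` at each state row (n, M).

        For mass action this is ``h_r / theta_r``; custom laws use the
        symbolic derivative of the supplied expression.
        """
        theta = self.theta if theta is None else theta
        states = np.atleast_2d(states)
        H = self.hazard_matrix(states, theta)
        D = H / theta[None, :]
        for r, (f, df) in self._custom_funcs().items():
            cols = [states[:, a].astype(float) for a in range(self.n_species)]
            D[:, r] = np.broadcast_to(df(theta[r], *cols), (states.shape[0],))
        return D

    @property
    def _cached_reactants(self):
        if "reactants" not in self._custom:
            self._custom["reactants"] = self._reactant_list()
        return self._custom["reactants"]

    def _kernel_pack(self):
        """Flat arrays for the compiled mass-action path evaluator, or None
        when any reaction has a custom rate law."""
        if "kernel" not in self._custom:
            if any(law != "mass_action" for law in self.rate_laws):
                self._custom["kernel"] = None
            else:
                ptr = [0]
                spec: list[int] = []
                stoich: list[int] = []
                invfact = np.ones(self.n_reactions)
                for r, pairs in enumerate(self._cached_reactants):
                    for a, u in pairs:
                        spec.append(a)
                        stoich.append(u)
                        if self.convention == "binomial":
                            invfact[r] /= math.factorial(u)
                    ptr.append(len(spec))
                self._custom["kernel"] = (
                    self.A.astype(np.int64),
                    np.array(ptr, dtype=np.int64),
                    np.array(spec, dtype=np.int64),
                    np.array(stoich, dtype=np.int64),
                    invfact,
                )
        return self._custom["kernel"]

    def restricted_net_effects(self, observed: Sequence[int]) -> np.ndarray:
        """Columns of A for the observed species (the matrix A-tilde)."""
        return self.A[:, list(observed)]


def _validate(network: ReactionNetwork) -> ReactionNetwork:
    U, V, A = network.U, network.V, network.A
    M, K = U.shape
    names = network.species_names
    if len(names) != K or len(set(names)) != K or any(not n for n in names):
        raise ModelSpecError("species names must be unique and non-empty")
    if V.shape != U.shape or A.shape != U.shape:
        raise ModelSpecError("U, V, A must share the shape (M, K)")
    for mat, tag in ((U, "U"), (V, "V")):
        if not np.issubdtype(mat.dtype, np.integer) or (mat < 0).any():
            raise ModelSpecError(f"{tag} must contain non-negative integers")
    if not np.array_equal(A, V - U):
        raise ModelSpecError("A must equal V - U")
    if network.theta.shape != (M,) or (network.theta <= 0).any() or not np.isfinite(network.theta).all():
        raise ModelSpecError("theta must be strictly positive and finite")
    if len(network.rate_laws) != M or len(network.reaction_names) != M:
        raise ModelSpecError("rate_laws and reaction_names need one entry per reaction")
    if network.convention not in CONVENTIONS:
        raise ModelSpecError(f"unknown mass-action convention {network.convention!r}")
    for idx, total in network.conserved:
        if total < 0 or any(i < 0 or i >= K for i in idx):
            raise ModelSpecError("conserved totals must reference valid species")
        if np.any(A[:, list(idx)].sum(axis=1) != 0):
            raise ModelSpecError("declared conserved total is not conserved by the stoichiometry")
    for law in network.rate_laws:
        if law != "mass_action":
            # force compilation now so malformed expressions fail at build time
            try:
                network._custom_funcs()
            except Exception as exc:  # pragma: no cover - sympy error text varies
                raise ModelSpecError(f"cannot parse custom rate law {law!r}: {exc}") from exc
            break
    return network


def build_network(spec: dict) -> ReactionNetwork:
    """Build and validate a :class:`ReactionNetwork` from a plain description.

    ``spec`` uses the documented schema::

        {"species": ["A", ...],
         "reactions": [{"name": "R1", "reactants": {"A": 1}, "products": {},
                        "rate_law": "mass_action", "theta": 0.03}, ...],
         "conserved": [{"species": ["DNA", "DNA.P2"], "total": 10}],   # optional
         "convention": "binomial"}                                     # optional
    """
    if "species" not in spec or "reactions" not in spec:
        raise ModelSpecError("model spec needs 'species' and 'reactions'")
    names = tuple(str(s) for s in spec["species"])
    K = len(names)
    index = {}
    for i, n in enumerate(names):
        if n in index:
            raise ModelSpecError(f"duplicate species {n!r}")
        index[n] = i
    reactions = spec["reactions"]
    M = len(reactions)
    if M == 0:
        raise ModelSpecError("at least one reaction is required")
    U = np.zeros((M, K), dtype=np.int64)
    V = np.zeros((M, K), dtype=np.int64)
    theta = np.empty(M)
    laws, rnames = [], []
    for r, rxn in enumerate(reactions):
        for side, mat in (("reactants", U), ("products", V)):
            for sname, stoich in dict(rxn.get(side, {})).items():
                if sname not in index:
                    raise ModelSpecError(f"reaction {r + 1} references unknown species {sname!r}")
                if int(stoich) != stoich or stoich < 0:
                    raise ModelSpecError(f"reaction {r + 1}: stoichiometry must be a non-negative integer")
                mat[r, index[sname]] = int(stoich)
        law = str(rxn.get("rate_law", "mass_action"))
        laws.append(law)
        rnames.append(str(rxn.get("name", f"R{r + 1}")))
        th = float(rxn.get("theta", np.nan))
        if not np.isfinite(th) or th <= 0:
            raise ModelSpecError(f"reaction {rnames[-1]}: theta must be > 0")
        theta[r] = th
    conserved = []
    for grp in spec.get("conserved", []):
        idx = tuple(index[s] for s in grp["species"])
        conserved.append((idx, int(grp["total"])))
    net = ReactionNetwork(
        species_names=names,
        U=U,
        V=V,
        A=V - U,
        theta=theta,
        rate_laws=tuple(laws),
        reaction_names=tuple(rnames),
        conserved=tuple(conserved),
        convention=str(spec.get("convention", "binomial")),
    )
    return _validate(net)


def hazards(network: ReactionNetwork, state) -> np.ndarray:
    """Functional form of :meth:`ReactionNetwork.hazards`."""
    return network.hazards(state)
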