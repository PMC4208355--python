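"""Reaction networks, propensities, conservation laws, state-space enumeration
and rate-matrix construction for Markov jump-process models of chemistry.

Conventions
-----------
* States are tuples of non-negative integer molecule counts, one per species.
* The generator ``Q`` is column-based: ``dP/dt = Q P`` with
  ``Q[to, from] = sum of propensities of reactions taking `from` to `to```,
  so an equilibrium distribution is a *right* nullvector of ``Q``.
* The homogeneous bimolecular propensity is ``kappa * X * (X - 1)`` with NO
  factor 1/2.  Other texts divide by two; the rate constants used here must
  follow this convention.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import poisson

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ConservationLaw",
    "StateSpace",
    "UnsupportedKineticsError",
    "TruncationRequiredError",
    "propensity",
    "stoichiometric_matrix",
    "conservation_laws",
    "enumerate_compatibility_class",
    "build_rate_matrix",
    "truncate_by_mass",
]

State = tuple  # tuple of non-negative ints, one entry per species


class UnsupportedKineticsError(ValueError):
    """Raised for reactions of order > 2 without an explicit propensity rule."""


class TruncationRequiredError(RuntimeError):
    """Raised when a compatibility class exceeds the allowed state budget."""


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel ``alpha -> beta`` with rate constant ``rate``.

    ``reactants`` and ``products`` are integer coefficient vectors over the
    network's species.  ``propensity_rule``, if given, overrides mass-action
    kinetics (required for reactions of order > 2).
    """

    reactants: tuple
    products: tuple
    rate: float
    propensity_rule: Optional[Callable[[State], float]] = field(
        default=None, compare=False
    )

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError(f"rate constant must be positive, got {self.rate}")
        if tuple(self.reactants) == tuple(self.products):
            raise ValueError("reactant and product complexes must differ")
        if any(c < 0 for c in self.reactants) or any(c < 0 for c in self.products):
            raise ValueError("stoichiometric coefficients must be non-negative")

    @property
    def order(self) -> int:
        return int(sum(self.reactants))

    @property
    def change(self) -> tuple:
        """State-change vector nu = beta - alpha."""
        return tuple(b - a for a, b in zip(self.reactants, self.products))


class ReactionNetwork:
    """An ordered collection of species and reaction channels."""

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        species = list(species)
        if len(set(species)) != len(species):
            raise ValueError("species names must be unique")
        n = len(species)
        merged: list[Reaction] = []
        index: dict[tuple, int] = {}
        for r in reactions:
            if len(r.reactants) != n or len(r.products) != n:
                raise ValueError("complex vector length must equal species count")
            key = (tuple(r.reactants), tuple(r.products))
            if key in index and r.propensity_rule is None:
                # identical Markov dynamics: merge by summing rate constants
                i = index[key]
                old = merged[i]
                merged[i] = Reaction(old.reactants, old.products, old.rate + r.rate)
            else:
                index[key] = len(merged)
                merged.append(r)
        self.species = species
        self.reactions = merged

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def __repr__(self):
        return (
            f"ReactionNetwork({len(self.species)} species, "
            f"{len(self.reactions)} reactions)"
        )


@dataclass(frozen=True)
class ConservationLaw:
    """Integer weight vector ``w`` with ``w @ nu == 0``; ``value = w @ X0``."""

    weights: tuple
    value: Optional[int] = None


@dataclass
class StateSpace:
    """Ordered enumeration of states with O(1) index lookup."""

    states: list
    index: dict = field(default_factory=dict)
    truncated: bool = False

    def __post_init__(self):
        if not self.index:
            self.index = {s: i for i, s in enumerate(self.states)}
        if len(self.index) != len(self.states):
            raise ValueError("states must be pairwise distinct")

    def __len__(self):
        return len(self.states)

    def __contains__(self, state):
        return tuple(state) in self.index

    def __iter__(self):
        return iter(self.states)


def propensity(network: ReactionNetwork, j: int, X: Sequence[int]) -> float:
    """Stochastic mass-action intensity of reaction ``j`` in state ``X``.

    Zeroth order: kappa; first order: kappa*X_i; heterogeneous bimolecular:
    kappa*X_i*X_k; homogeneous bimolecular: kappa*X_i*(X_i - 1).
    """
    r = network.reactions[j]
    if r.propensity_rule is not None:
        a = float(r.propensity_rule(tuple(X)))
        if a < 0:
            raise ValueError("propensity rule returned a negative intensity")
        return a
    if any(x < a for x, a in zip(X, r.reactants)):
        return 0.0
    order = r.order
    if order == 0:
        return r.rate
    if order == 1:
        i = next(k for k, a in enumerate(r.reactants) if a)
        return r.rate * X[i]
    if order == 2:
        idx = [k for k, a in enumerate(r.reactants) for _ in range(a)]
        i, k = idx
        if i == k:
            return r.rate * X[i] * (X[i] - 1)
        return r.rate * X[i] * X[k]
    raise UnsupportedKineticsError(
        f"reaction {j} has order {order} > 2 and no explicit propensity rule"
    )


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer matrix with column j equal to products_j - reactants_j."""
    if network.n_reactions == 0:
        raise ValueError("network has no reactions")
    return np.array(
        [r.change for r in network.reactions], dtype=np.int64
    ).T.reshape(network.n_species, network.n_reactions)


def conservation_laws(network: ReactionNetwork) -> list[ConservationLaw]:
    """Integer basis of the left nullspace of the stoichiometric matrix.

    Exact rational elimination; each basis vector is scaled to coprime
    integers with positive leading entry.
    """
    nu = stoichiometric_matrix(network)
    basis = _integer_left_nullspace(nu)
    return [ConservationLaw(tuple(int(x) for x in w)) for w in basis]


def _integer_left_nullspace(nu: np.ndarray) -> list[np.ndarray]:
    import sympy

    M = sympy.Matrix(nu.tolist()).T  # right nullspace of nu^T = left nullspace of nu
    out = []
    for v in M.nullspace():
        denoms = [Fraction(sympy.Rational(x)).denominator for x in v]
        lcm = 1
        for d in denoms:
            lcm = lcm * d // np.gcd(lcm, d)
        ints = [int(x * lcm) for x in v]
        g = 0
        for x in ints:
            g = np.gcd(g, abs(x))
        ints = [x // g for x in ints]
        lead = next(x for x in ints if x != 0)
        if lead < 0:
            ints = [-x for x in ints]
        out.append(np.array(ints, dtype=np.int64))
    return out


def enumerate_compatibility_class(
    network: ReactionNetwork,
    X0: Sequence[int],
    max_states: int = 100_000,
) -> StateSpace:
    """Breadth-first closure of ``X0`` under reactions fired in either
    direction (counts kept non-negative).

    Deterministic order: BFS from X0, neighbours visited in reaction-index
    order (forward jump before reverse jump for each reaction).
    """
    X0 = tuple(int(x) for x in X0)
    if any(x < 0 for x in X0):
        raise ValueError("initial state must be non-negative")
    changes = [r.change for r in network.reactions]
    seen = {X0}
    order = [X0]
    queue = deque([X0])
    while queue:
        x = queue.popleft()
        for nu in changes:
            for sgn in (1, -1):
                y = tuple(xi + sgn * di for xi, di in zip(x, nu))
                if any(v < 0 for v in y) or y in seen:
                    continue
                seen.add(y)
                order.append(y)
                queue.append(y)
                if len(order) > max_states:
                    raise TruncationRequiredError(
                        f"compatibility class exceeds max_states={max_states}; "
                        "truncate (e.g. truncate_by_mass) or raise the bound"
                    )
    return StateSpace(order)


def build_rate_matrix(network: ReactionNetwork, space: StateSpace) -> sp.csc_matrix:
    """Column-generator Q on ``space``: Q[to, from] = propensity, columns sum
    to zero.  Transitions leaving the space are dropped together with their
    rate (reflecting truncation), so Q remains a proper generator.
    """
    n = len(space)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i_from, x in enumerate(space.states):
        for j in range(network.n_reactions):
            a = propensity(network, j, x)
            if a == 0.0:
                continue
            y = tuple(xi + di for xi, di in zip(x, network.reactions[j].change))
            i_to = space.index.get(y)
            if i_to is None:
                continue  # reflecting truncation: drop rate out of the space
            rows.append(i_to)
            cols.append(i_from)
            vals.append(a)
            diag[i_from] -= a
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    Q = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    Q.sum_duplicates()
    return Q


def _is_birth_death(network: ReactionNetwork):
    """Detect a single-species (0 -> S, S -> 0) network; return (kb, kd)."""
    if network.n_species != 1 or network.n_reactions != 2:
        return None
    kb = kd = None
    for r in network.reactions:
        if r.reactants == (0,) and r.products == (1,):
            kb = r.rate
        elif r.reactants == (1,) and r.products == (0,):
            kd = r.rate
    if kb is None or kd is None:
        return None
    return kb, kd


def truncate_by_mass(
    network: ReactionNetwork,
    X0: Sequence[int],
    eps: float,
    max_states: int = 100_000,
) -> StateSpace:
    """Smallest prefix of the enumerated class carrying equilibrium mass
    >= 1 - eps.

    For the birth-death network the Poisson(kappa_b/kappa_d) tail fixes the
    cut exactly; otherwise the space is grown geometrically and the
    reflecting-truncated equilibrium is used to locate the cut.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    bd = _is_birth_death(network)
    if bd is not None:
        lam = bd[0] / bd[1]
        K = int(poisson.ppf(1 - eps, lam))
        while poisson.cdf(K, lam) < 1 - eps:  # guard against ppf edge cases
            K += 1
        return StateSpace([(i,) for i in range(K + 1)], truncated=True)
    # finite class: no truncation needed if it fits
    try:
        return enumerate_compatibility_class(network, X0, max_states=max_states)
    except TruncationRequiredError:
        pass
    from .solvers import equilibrium_nullspace  # local import: avoid cycle

    size = 256
    while size <= max_states:
        space = _enumerate_capped(network, X0, size)
        Q = build_rate_matrix(network, space)
        dists = equilibrium_nullspace(Q)
        if len(dists) == 1:
            probs = dists[0].probs
            csum = np.cumsum(probs)
            k = int(np.searchsorted(csum, 1 - eps)) + 1
            if k < 0.9 * len(space):  # cut well inside the window: accept
                return StateSpace(space.states[:k], truncated=True)
        size *= 2
    raise TruncationRequiredError("could not locate a mass cut within max_states")


def _enumerate_capped(network, X0, cap):
    """BFS enumeration that stops (instead of raising) at ``cap`` states."""
    X0 = tuple(int(x) for x in X0)
    changes = [r.change for r in network.reactions]
    seen = {X0}
    order = [X0]
    queue = deque([X0])
    while queue and len(order) < cap:
        x = queue.popleft()
        for nu in changes:
            for sgn in (1, -1):
                y = tuple(xi + sgn * di for xi, di in zip(x, nu))
                if any(v < 0 for v in y) or y in seen:
                    continue
                seen.add(y)
                order.append(y)
                queue.append(y)
                if len(order) >= cap:
                    break
            if len(order) >= cap:
                break
    return StateSpace(order, truncated=True)
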