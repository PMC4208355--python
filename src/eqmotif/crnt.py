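"""Chemical reaction network theory: complex graph, linkage classes, weak
reversibility, deficiency, complex-balanced steady states and product-form
(conditional Poisson) equilibria.

The deterministic side uses monomial mass action c**alpha; the stochastic
side uses falling-factorial propensities.  The mismatch is deliberate: the
product-form theorem couples the deterministic complex-balanced state c to
the stochastic equilibrium pi(X) ~ prod_i c_i**X_i / X_i!.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln, logsumexp

from .network import ReactionNetwork, StateSpace, stoichiometric_matrix
from .solvers import EquilibriumDistribution

__all__ = [
    "ComplexGraph",
    "CRNTReport",
    "ComplexBalancedState",
    "NoBalanceFoundError",
    "complex_graph",
    "crnt_report",
    "complex_balanced_state",
    "product_form_equilibrium",
    "mass_action_ode_rhs",
]


class NoBalanceFoundError(RuntimeError):
    pass


@dataclass
class ComplexGraph:
    """Directed graph on the distinct complexes of a network; one edge per
    reaction channel from reactant to product complex."""

    complexes: list  # tuples, deduplicated in first-occurrence order
    edges: list  # (from_idx, to_idx, reaction_idx)

    @property
    def n_complexes(self):
        return len(self.complexes)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(range(self.n_complexes))
        for a, b, j in self.edges:
            g.add_edge(a, b, reaction=j)
        return g


@dataclass(frozen=True)
class CRNTReport:
    n_complexes: int
    n_linkage_classes: int
    stoich_dim: int
    deficiency: int
    weakly_reversible: bool


@dataclass
class ComplexBalancedState:
    """Strictly positive concentration vector with per-complex production
    and consumption rates balanced to within ``residual`` (relative)."""

    c: np.ndarray
    residual: float


def complex_graph(network: ReactionNetwork) -> ComplexGraph:
    complexes: list = []
    index: dict = {}
    for r in network.reactions:
        for z in (tuple(r.reactants), tuple(r.products)):
            if z not in index:
                index[z] = len(complexes)
                complexes.append(z)
    edges = [
        (index[tuple(r.reactants)], index[tuple(r.products)], j)
        for j, r in enumerate(network.reactions)
    ]
    return ComplexGraph(complexes, edges)


def crnt_report(network: ReactionNetwork) -> CRNTReport:
    """Deficiency = #complexes - #linkage classes - dim Im(nu); weakly
    reversible iff every linkage class is strongly connected."""
    cg = complex_graph(network)
    g = cg.to_networkx()
    n_link = nx.number_weakly_connected_components(g)
    wr = all(
        len(list(nx.strongly_connected_components(g.subgraph(comp)))) == 1
        for comp in nx.weakly_connected_components(g)
    )
    import sympy

    nu = stoichiometric_matrix(network)
    stoich_dim = int(sympy.Matrix(nu.tolist()).rank())
    deficiency = cg.n_complexes - n_link - stoich_dim
    return CRNTReport(cg.n_complexes, n_link, stoich_dim, deficiency, wr)


def _complex_balance_residuals(network: ReactionNetwork, log_c: np.ndarray):
    """Per-complex (production - consumption) rates at c = exp(log_c),
    using monomial mass action c**alpha, scaled by the complex's total
    throughput (so residuals are relative)."""
    cg = complex_graph(network)
    alphas = np.array([r.reactants for r in network.reactions], dtype=float)
    kappas = np.array([r.rate for r in network.reactions])
    log_rates = np.log(kappas) + alphas @ log_c
    # a global multiplicative shift cancels in the relative residual; use it
    # to keep exp() in range for wandering optimizer iterates
    rates = np.exp(log_rates - log_rates.max())
    res = np.zeros(cg.n_complexes)
    scale = np.zeros(cg.n_complexes)
    for a, b, j in cg.edges:
        res[a] -= rates[j]  # complex a consumed by reaction j
        res[b] += rates[j]  # complex b produced by reaction j
        scale[a] += rates[j]
        scale[b] += rates[j]
    return res / np.maximum(scale, 1e-300)


def _log_c_via_complex_graph(network: ReactionNetwork):
    """Deterministic route: complex balance says A_kappa psi(c) = 0 with
    A_kappa the weighted Laplacian of the complex graph and
    psi(c)_zeta = c**zeta.  Find the positive nullvector per (strongly
    connected) linkage class, then solve the log-linear system
    zeta . y - lambda_l = log psi_zeta for the log-concentrations y and one
    free scale per class.  Consistent exactly when deficiency is zero."""
    from .solvers import IllConditionedError, _solve_single_class

    cg = complex_graph(network)
    K = cg.n_complexes
    A = np.zeros((K, K))
    for a, b, j in cg.edges:
        kappa = network.reactions[j].rate
        A[b, a] += kappa
        A[a, a] -= kappa
    g = cg.to_networkx()
    comps = list(nx.weakly_connected_components(g))
    n = network.n_species
    rows, rhs = [], []
    for l, comp in enumerate(comps):
        idx = np.array(sorted(comp))
        sub = A[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, -sub.sum(axis=0))
        try:
            psi = _solve_single_class(sub)
        except IllConditionedError:
            return None  # class not strongly connected: not weakly reversible
        if np.any(psi <= 0):
            return None
        for z, p in zip(idx, psi):
            row = np.zeros(n + len(comps))
            row[:n] = cg.complexes[z]
            row[n + l] = -1.0
            rows.append(row)
            rhs.append(np.log(p))
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return sol[:n]


def complex_balanced_state(
    network: ReactionNetwork,
    tol: float = 1e-10,
    n_starts: int = 10,
    seed: int = 0,
) -> ComplexBalancedState:
    """Find a strictly positive concentration vector balancing every
    complex's production and consumption.

    Tries the deterministic complex-graph route first (exact for weakly
    reversible deficiency-zero networks), then falls back to seeded
    multistart least squares in log-concentration space.  Failure raises
    :class:`NoBalanceFoundError` (consistent with deficiency > 0 or lack of
    weak reversibility).
    """
    n = network.n_species
    best = None
    y = _log_c_via_complex_graph(network)
    if y is not None:
        resid = float(np.abs(_complex_balance_residuals(network, y)).max())
        best = (y, resid)
    if best is None or best[1] >= tol:
        rng = np.random.default_rng(seed)
        for k in range(n_starts):
            x0 = np.zeros(n) if k == 0 else rng.normal(scale=1.5, size=n)
            sol = least_squares(
                lambda v: _complex_balance_residuals(network, v),
                x0,
                method="lm",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
            resid = float(np.abs(_complex_balance_residuals(network, sol.x)).max())
            if best is None or resid < best[1]:
                best = (sol.x, resid)
            if resid < tol:
                break
    log_c, resid = best
    if resid >= tol:
        raise NoBalanceFoundError(
            f"no complex-balanced state found (best relative residual {resid:.2e}); "
            "consistent with deficiency > 0 or lack of weak reversibility"
        )
    return ComplexBalancedState(np.exp(log_c), resid)


def product_form_equilibrium(
    network: ReactionNetwork,
    c: ComplexBalancedState | np.ndarray,
    space: StateSpace,
) -> EquilibriumDistribution:
    """Conditional product-of-Poissons equilibrium on one compatibility
    class: pi(X) ~ prod_i c_i**X_i / X_i!, normalized over ``space``
    (log-space accumulation).  Independent of which complex-balanced c is
    supplied."""
    cv = np.asarray(c.c if isinstance(c, ComplexBalancedState) else c, dtype=float)
    if cv.ndim != 1 or cv.size != network.n_species:
        raise ValueError("c must have one entry per species")
    if np.any(cv <= 0):
        raise ValueError("c must be strictly positive")
    X = np.array(space.states, dtype=float)
    logw = X @ np.log(cv) - gammaln(X + 1.0).sum(axis=1)
    logZ = logsumexp(logw)
    return EquilibriumDistribution(np.exp(logw - logZ), space)


def mass_action_ode_rhs(network: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """Deterministic reaction-rate equation dc/dt = nu @ (kappa * c**alpha)."""
    cv = np.asarray(c, dtype=float)
    nu = stoichiometric_matrix(network).astype(float)
    alphas = np.array([r.reactants for r in network.reactions], dtype=float)
    kappas = np.array([r.rate for r in network.reactions])
    rates = kappas * np.prod(cv[np.newaxis, :] ** alphas, axis=1)
    return nu @ rates
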