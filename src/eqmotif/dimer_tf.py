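"""Gene regulated by dimer transcription factors on a ladder-shaped state
space: 2M <-> D (dimerization) and G + D <-> G* (binding).

With T monomers total and a single gene copy, the conserved quantities are
T = M + 2D + 2G* and G + G* = 1; the state is indexed by (d, g) with d the
total dimer count (free plus bound) and g in {0, 1} the gene state.  The
free side of the ladder has d in {0..floor(T/2)}, the bound side
d in {1..floor(T/2)} — one side is longer than the other.

The network is reversible with four complexes, two linkage classes and a
two-dimensional stoichiometric subspace, hence deficiency zero, so the
exact equilibrium is the conditional product-of-Poissons built from the
complex-balanced state c_M = 1, c_D = k1/km1, c_G = 1, c_G* = kb*c_D/ku.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.special import gammaln, logsumexp

from .network import Reaction, ReactionNetwork, StateSpace
from .solvers import EquilibriumDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "dimer_tf_network",
    "ladder_space",
    "exact_ladder_equilibrium",
    "exact_gene_free_prob",
    "asymptotic_gene_free_prob",
    "ode_steady_state_dimers",
]

SPECIES = ("M", "D", "G", "Gs")


def dimer_tf_network(
    T: int, kappa_1: float, kappa_minus1: float, kappa_b: float, kappa_u: float
) -> tuple[ReactionNetwork, StateSpace]:
    """Four-species network over (M, D, G, Gs) and its ladder-ordered
    compatibility class (free side d = 0..N, then bound side d = 1..N)."""
    if T < 2:
        raise ValueError("T must be >= 2 (binding unreachable otherwise)")
    for name, v in [
        ("kappa_1", kappa_1), ("kappa_minus1", kappa_minus1),
        ("kappa_b", kappa_b), ("kappa_u", kappa_u),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    net = ReactionNetwork(
        list(SPECIES),
        [
            Reaction((2, 0, 0, 0), (0, 1, 0, 0), kappa_1),
            Reaction((0, 1, 0, 0), (2, 0, 0, 0), kappa_minus1),
            Reaction((0, 1, 1, 0), (0, 0, 0, 1), kappa_b),
            Reaction((0, 0, 0, 1), (0, 1, 1, 0), kappa_u),
        ],
    )
    return net, ladder_space(T)


def ladder_space(T: int) -> StateSpace:
    """States (M, D, G, Gs) ordered free side first (d = 0..N), then bound
    side (d = 1..N); size 2*floor(T/2) + 1."""
    N = T // 2
    states = [(T - 2 * d, d, 1, 0) for d in range(N + 1)]
    states += [(T - 2 * d, d - 1, 0, 1) for d in range(1, N + 1)]
    return StateSpace(states)


def _log_weights(T, kappa_1, kappa_minus1, kappa_b, kappa_u):
    """Unnormalized log product-form weights on the ladder (free side,
    bound side), using c_M = c_G = 1, c_D = k1/km1, c_G* = kb*c_D/ku."""
    N = T // 2
    log_cD = np.log(kappa_1) - np.log(kappa_minus1)
    log_cGs = np.log(kappa_b) + log_cD - np.log(kappa_u)
    d_free = np.arange(N + 1)
    lw_free = d_free * log_cD - gammaln(d_free + 1) - gammaln(T - 2 * d_free + 1)
    d_bnd = np.arange(1, N + 1)
    lw_bnd = (
        (d_bnd - 1) * log_cD - gammaln(d_bnd) - gammaln(T - 2 * d_bnd + 1) + log_cGs
    )
    return lw_free, lw_bnd


def exact_ladder_equilibrium(
    T: int, kappa_1: float, kappa_minus1: float, kappa_b: float, kappa_u: float
) -> EquilibriumDistribution:
    """Exact product-form equilibrium on the ladder, in ladder_space order."""
    net, space = dimer_tf_network(T, kappa_1, kappa_minus1, kappa_b, kappa_u)
    lw_free, lw_bnd = _log_weights(T, kappa_1, kappa_minus1, kappa_b, kappa_u)
    lw = np.concatenate([lw_free, lw_bnd])
    probs = np.exp(lw - logsumexp(lw))
    return EquilibriumDistribution(probs, space)


def exact_gene_free_prob(
    T: int, kappa_1: float, kappa_minus1: float, kappa_b: float, kappa_u: float
) -> float:
    """Pr_T(G* = 0): marginal of the exact ladder equilibrium over dimer
    counts, computed in log space (stable for large T)."""
    if T < 2:
        raise ValueError("T must be >= 2")
    lw_free, lw_bnd = _log_weights(T, kappa_1, kappa_minus1, kappa_b, kappa_u)
    l0 = logsumexp(lw_free)
    l1 = logsumexp(lw_bnd)
    return float(np.exp(l0 - np.logaddexp(l0, l1)))


def asymptotic_gene_free_prob(T: int, kappa_b: float, kappa_u: float) -> float:
    """Saddle-point asymptotic for Pr_T(G* = 0), a function of kappa_b,
    kappa_u and T only.

    To the accuracy the saddle-point method supports, the dimer pool behaves
    like T/2 monomer TFs feeding the single-site binding equilibrium, giving
    kappa_u / (kappa_u + kappa_b * T / 2); the dimerization constants only
    enter through a sqrt(T)-order correction that the method cannot resolve.
    The value is clipped to [0, 1] with a warning, since truncating the
    expansion can leave the unit interval at small T (raising T always
    remedies this).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    val = kappa_u / (kappa_u + kappa_b * T / 2.0)
    if val > 1.0 or val < 0.0:
        warnings.warn(
            f"asymptotic gene-free probability {val} clipped to [0, 1]; "
            "increase T for a usable approximation",
            RuntimeWarning,
        )
        val = min(max(val, 0.0), 1.0)
    return float(val)


def ode_steady_state_dimers(T: float, kappa_1: float, kappa_minus1: float) -> float:
    """Deterministic steady-state dimer count: solve kappa_1 m^2 =
    kappa_minus1 d with m + 2d = T in closed form and return d.

    d = T/2 - m/2 with m the positive root of
    2*kappa_1*m^2 + kappa_minus1*m - kappa_minus1*T = 0, so the deficit
    from the maximum T/2 is of order sqrt(T).
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    m = (
        -kappa_minus1 + np.sqrt(kappa_minus1**2 + 8.0 * kappa_1 * kappa_minus1 * T)
    ) / (4.0 * kappa_1)
    return float((T - m) / 2.0)
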