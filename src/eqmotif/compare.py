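"""Comparison of four gene-regulation mechanisms: probability that all
TF binding sites of a single gene are occupied, as a function of the TF
(or monomer) count T.

Mechanisms
----------
monomer      one site, monomer TFs            (rates kappa_b, kappa_u)
dimer        one site, dimer TFs built from T monomers
             (kappa_1, kappa_minus1, kappa_b, kappa_u); exact ladder
             computation by default, saddle-point asymptotic opt-in
sequential   two sites, fixed binding order   (kappa_0, kappa_1,
             kappa_minus1, kappa_minus2)
independent  two sites, either order          (same rate names)

Series are expansions of the occupancy *deficit* 1 - Pr(fully bound) in
powers of 1/T; the exact rational curve is the ground truth the series are
checked against.  The dimer mechanism supports the leading order only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import sympy

from .dimer_tf import asymptotic_gene_free_prob, exact_gene_free_prob
from .motifs import independent_two_sites, sequential_two_sites

MECHANISMS = ("monomer", "dimer", "sequential", "independent")

__all__ = [
    "OccupancyCurve",
    "UnsupportedPrecisionError",
    "full_occupancy_prob",
    "occupancy_curve",
    "series_expansion",
    "evaluate_series",
    "sequential_independent_equivalence",
    "MECHANISMS",
]


class UnsupportedPrecisionError(ValueError):
    """Dimer-mechanism series beyond the leading order are not available."""


@dataclass
class OccupancyCurve:
    mechanism: str
    T_values: np.ndarray
    probabilities: np.ndarray
    series_coefficients: Optional[list] = field(default=None)

    def __post_init__(self):
        self.T_values = np.asarray(self.T_values)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.T_values) <= 0):
            raise ValueError("T grid must be increasing")
        if np.any((self.probabilities < -1e-12) | (self.probabilities > 1 + 1e-12)):
            raise ValueError("probabilities must lie in [0, 1]")


def full_occupancy_prob(
    mechanism: str, T: int, rates: dict, dimer_asymptotic: bool = False
) -> float:
    """Pr(all sites of the gene occupied) for one mechanism at one T."""
    if mechanism == "monomer":
        kb, ku = rates["kappa_b"], rates["kappa_u"]
        return kb * T / (ku + kb * T)
    if mechanism == "dimer":
        if dimer_asymptotic:
            return 1.0 - asymptotic_gene_free_prob(T, rates["kappa_b"], rates["kappa_u"])
        return 1.0 - exact_gene_free_prob(
            T, rates["kappa_1"], rates["kappa_minus1"],
            rates["kappa_b"], rates["kappa_u"],
        )
    if mechanism == "sequential":
        res = sequential_two_sites(
            T, rates["kappa_0"], rates["kappa_1"],
            rates["kappa_minus1"], rates["kappa_minus2"],
        )
        return float(res.closed_form.probs[-1])
    if mechanism == "independent":
        res = independent_two_sites(
            T, rates["kappa_0"], rates["kappa_1"],
            rates["kappa_minus1"], rates["kappa_minus2"],
        )
        return float(res.closed_form.probs[-1])
    raise ValueError(f"unknown mechanism {mechanism!r}")


def occupancy_curve(
    mechanism: str,
    T_grid: Sequence[int],
    rates: dict,
    series_order: Optional[int] = None,
    dimer_asymptotic: bool = False,
) -> OccupancyCurve:
    probs = [full_occupancy_prob(mechanism, int(T), rates, dimer_asymptotic)
             for T in T_grid]
    coeffs = series_expansion(mechanism, rates, series_order) if series_order else None
    return OccupancyCurve(mechanism, np.asarray(T_grid), np.asarray(probs), coeffs)


def _symbolic_deficit(mechanism: str, rates: dict):
    """Deficit 1 - Pr(fully bound) as an exact sympy expression in T."""
    T = sympy.Symbol("T", positive=True)
    R = {k: sympy.Rational(v) if float(v).is_integer() else sympy.Float(v, 30)
         for k, v in rates.items()}
    if mechanism == "monomer":
        return R["kappa_u"] / (R["kappa_u"] + R["kappa_b"] * T), T
    if mechanism == "sequential":
        p0, p1 = R["kappa_0"] * T, R["kappa_1"] * (T - 1)
        q1, q2 = R["kappa_minus1"], R["kappa_minus2"]
        w = [sympy.Integer(1), p0 / q1, p0 * p1 / (q1 * q2)]
        return (w[0] + w[1]) / sum(w), T
    if mechanism == "independent":
        w1 = R["kappa_0"] * T / R["kappa_minus1"]
        w3 = w1 * R["kappa_1"] * (T - 1) / R["kappa_minus2"]
        return (1 + 2 * w1) / (1 + 2 * w1 + w3), T
    if mechanism == "dimer":
        # only the saddle-point leading behaviour is available
        return 2 * R["kappa_u"] / (2 * R["kappa_u"] + R["kappa_b"] * T), T
    raise ValueError(f"unknown mechanism {mechanism!r}")


def series_expansion(mechanism: str, rates: dict, order: int = 2) -> list:
    """Coefficients [c0, c1, ..., c_order] of the deficit
    1 - Pr(fully bound) = sum_k c_k * (1/T)**k + O(T**-(order+1)).

    For the dimer mechanism only the leading (order-1) term is meaningful;
    requesting more raises :class:`UnsupportedPrecisionError`.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if mechanism == "dimer" and order > 1:
        raise UnsupportedPrecisionError(
            "dimer-TF series is only available to leading order"
        )
    expr, T = _symbolic_deficit(mechanism, rates)
    u = sympy.Symbol("u", positive=True)
    series = sympy.series(expr.subs(T, 1 / u), u, 0, order + 1).removeO()
    poly = sympy.Poly(sympy.expand(series), u)
    coeffs = [float(poly.coeff_monomial(u**k)) for k in range(order + 1)]
    return coeffs


def evaluate_series(coeffs: Sequence[float], T) -> np.ndarray:
    """Evaluate a deficit series at (an array of) T; returns the deficit."""
    T = np.asarray(T, dtype=float)
    u = 1.0 / T
    out = np.zeros_like(u)
    for k, c in enumerate(coeffs):
        out += c * u**k
    return out


def sequential_independent_equivalence(
    T: int,
    kappa_0: float,
    kappa_1: float,
    kappa_minus1: float,
    kappa_minus2: float,
    rescale: bool = True,
    tol: float = 1e-12,
) -> tuple[bool, float]:
    """Check the structural equivalence of the two two-site mechanisms.

    With ``rescale`` (the claim being tested): divide kappa_0 and
    kappa_minus2 by 2 in the independent model, sum its two singly-bound
    states, and compare with the sequential model's three-state
    distribution.  Returns (equal within tol, max abs deviation).
    """
    seq = sequential_two_sites(T, kappa_0, kappa_1, kappa_minus1, kappa_minus2)
    k0 = kappa_0 / 2 if rescale else kappa_0
    km2 = kappa_minus2 / 2 if rescale else kappa_minus2
    ind = independent_two_sites(T, k0, kappa_1, kappa_minus1, km2)
    p = ind.closed_form.probs
    aggregated = np.array([p[0], p[1] + p[2], p[3]])
    dev = float(np.abs(aggregated - seq.closed_form.probs).max())
    return dev < tol, dev
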