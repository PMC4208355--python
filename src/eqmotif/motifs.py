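"""Catalogue of biochemical motifs with known closed-form equilibria.

Each constructor returns a :class:`MotifResult` holding the explicit
reaction network (when one exists), the enumerated state space in the order
matching the closed form, and the closed-form equilibrium distribution.

Motifs
------
birth_death            constitutive production/degradation -> Poisson
isomerization          two-conformation molecule pool -> Binomial
tf_binding             TF binding to N gene copies -> path product formula
dimerization           monomer/dimer pool -> path formula (even/odd branch)
single_gene_tf         one gene, T TFs -> Bernoulli (Hill coefficient 1)
sequential_two_sites   ordered two-site binding -> three-state path
independent_two_sites  unordered two-site binding -> four-state cycle
hypercube_compounded   N independent sites, occupancy-compounded path
glued_three_site       three sites, one order-constrained -> glued chain
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.stats import binom, poisson

from .network import (
    Reaction,
    ReactionNetwork,
    StateSpace,
    build_rate_matrix,
    truncate_by_mass,
)
from .solvers import EquilibriumDistribution, PathRates, equilibrium_cycle, equilibrium_path

logger = logging.getLogger(__name__)

__all__ = [
    "MotifResult",
    "birth_death",
    "isomerization",
    "tf_binding",
    "dimerization",
    "single_gene_tf",
    "sequential_two_sites",
    "independent_two_sites",
    "hypercube_compounded",
    "hypercube_rate_matrix",
    "glued_three_site",
]


@dataclass
class MotifResult:
    """A motif's explicit model together with its analytic equilibrium."""

    closed_form: EquilibriumDistribution
    network: Optional[ReactionNetwork] = None
    space: Optional[StateSpace] = None
    parameterization: dict = field(default_factory=dict)
    rate_matrix: Optional[sp.spmatrix] = None  # set when no mass-action network exists

    def oracle_rate_matrix(self) -> sp.spmatrix:
        if self.rate_matrix is not None:
            return self.rate_matrix
        return build_rate_matrix(self.network, self.space)


def _positive(**kwargs):
    for name, v in kwargs.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")


def birth_death(kappa_b: float, kappa_d: float, eps: float = 1e-12) -> MotifResult:
    """0 -> S at rate kappa_b, S -> 0 at rate kappa_d * X.

    Equilibrium: Poisson(kappa_b / kappa_d), renormalized on the
    eps-truncated prefix {0..K} of the infinite path.
    """
    _positive(kappa_b=kappa_b, kappa_d=kappa_d)
    net = ReactionNetwork(
        ["S"],
        [Reaction((0,), (1,), kappa_b), Reaction((1,), (0,), kappa_d)],
    )
    space = truncate_by_mass(net, (0,), eps)
    lam = kappa_b / kappa_d
    pmf = poisson.pmf(np.arange(len(space)), lam)
    dist = EquilibriumDistribution(pmf / pmf.sum(), space)
    return MotifResult(
        dist, net, space,
        {"kappa_b": kappa_b, "kappa_d": kappa_d, "lambda": lam, "eps": eps},
    )


def isomerization(N: int, kappa_plus: float, kappa_minus: float) -> MotifResult:
    """S1 <-> S2 with N molecules total; i = count of S1.

    S2 -> S1 carries kappa_plus (it increases i), S1 -> S2 carries
    kappa_minus.  Equilibrium: Binomial(N, kappa_plus/(kappa_plus+kappa_minus)).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    _positive(kappa_plus=kappa_plus, kappa_minus=kappa_minus)
    net = ReactionNetwork(
        ["S1", "S2"],
        [
            Reaction((0, 1), (1, 0), kappa_plus),
            Reaction((1, 0), (0, 1), kappa_minus),
        ],
    )
    space = StateSpace([(i, N - i) for i in range(N + 1)])
    prob = kappa_plus / (kappa_plus + kappa_minus)
    pmf = binom.pmf(np.arange(N + 1), N, prob)
    dist = EquilibriumDistribution(pmf / pmf.sum(), space)
    return MotifResult(
        dist, net, space,
        {"N": N, "kappa_plus": kappa_plus, "kappa_minus": kappa_minus, "p": prob},
    )


def tf_binding(N: int, T: int, kappa_b: float, kappa_u: float) -> MotifResult:
    """TFs binding N gene copies: G + F -> Gs (kappa_b), Gs -> G + F (kappa_u).

    i = number of bound genes in {0..N}; detailed balance gives
    kappa_u (i+1) pi_{i+1} = kappa_b (N-i)(T-i) pi_i, normalized with the
    Horner nested sum.  Requires N <= T; larger N is handled by swapping the
    roles of gene and TF.
    """
    if N < 1 or T < 1:
        raise ValueError("N and T must be >= 1")
    _positive(kappa_b=kappa_b, kappa_u=kappa_u)
    if N > T:
        logger.info("tf_binding: N=%d > T=%d, swapping gene and TF roles", N, T)
        N, T = T, N
    net = ReactionNetwork(
        ["F", "G", "Gs"],
        [
            Reaction((1, 1, 0), (0, 0, 1), kappa_b),
            Reaction((0, 0, 1), (1, 1, 0), kappa_u),
        ],
    )
    space = StateSpace([(T - i, N - i, i) for i in range(N + 1)])
    p = [kappa_b * (N - i) * (T - i) for i in range(N)]
    q = [kappa_u * (i + 1) for i in range(N)]
    dist = equilibrium_path(PathRates(tuple(p), tuple(q)))
    dist.space = space
    return MotifResult(
        dist, net, space,
        {"N": N, "T": T, "kappa_b": kappa_b, "kappa_u": kappa_u},
    )


def dimerization(total_monomers: int, kappa_b: float, kappa_u: float) -> MotifResult:
    """2M -> D (kappa_b), D -> 2M (kappa_u); i = dimer count.

    Forward rate p_i = kappa_b * m * (m - 1) with m = total - 2i free
    monomers (even and odd branches fall out of the same expression),
    backward q_i = kappa_u * i.
    """
    if total_monomers < 2:
        raise ValueError("total_monomers must be >= 2")
    _positive(kappa_b=kappa_b, kappa_u=kappa_u)
    net = ReactionNetwork(
        ["M", "D"],
        [
            Reaction((2, 0), (0, 1), kappa_b),
            Reaction((0, 1), (2, 0), kappa_u),
        ],
    )
    N = total_monomers // 2
    space = StateSpace([(total_monomers - 2 * i, i) for i in range(N + 1)])
    p = [
        kappa_b * (total_monomers - 2 * i) * (total_monomers - 2 * i - 1)
        for i in range(N)
    ]
    q = [kappa_u * (i + 1) for i in range(N)]
    dist = equilibrium_path(PathRates(tuple(p), tuple(q)))
    dist.space = space
    return MotifResult(
        dist, net, space,
        {
            "total_monomers": total_monomers,
            "N": N,
            "kappa_b": kappa_b,
            "kappa_u": kappa_u,
            "parity": "even" if total_monomers % 2 == 0 else "odd",
        },
    )


def single_gene_tf(T: int, kappa_b: float, kappa_u: float) -> MotifResult:
    """One gene, T TFs: Bernoulli with
    Pr(bound) = kappa_b*T / (kappa_u + kappa_b*T), a Hill function with
    Hill coefficient 1 in T."""
    if T < 0:
        raise ValueError("T must be >= 0")
    _positive(kappa_b=kappa_b, kappa_u=kappa_u)
    p_bound = kappa_b * T / (kappa_u + kappa_b * T)
    net = ReactionNetwork(
        ["F", "G", "Gs"],
        [
            Reaction((1, 1, 0), (0, 0, 1), kappa_b),
            Reaction((0, 0, 1), (1, 1, 0), kappa_u),
        ],
    )
    if T == 0:
        space = StateSpace([(0, 1, 0)])
        dist = EquilibriumDistribution(np.array([1.0]), space)
    else:
        space = StateSpace([(T, 1, 0), (T - 1, 0, 1)])
        dist = EquilibriumDistribution(np.array([1.0 - p_bound, p_bound]), space)
    return MotifResult(
        dist, net, space,
        {"T": T, "kappa_b": kappa_b, "kappa_u": kappa_u, "p_bound": p_bound},
    )


def sequential_two_sites(
    T: int,
    kappa_0: float,
    kappa_1: float,
    kappa_minus1: float,
    kappa_minus2: float,
    helpers: Optional[int] = None,
) -> MotifResult:
    """Gene with two sites bound in a fixed order: three-state path
    (empty, one bound, both bound).

    Without helpers: p_0 = kappa_0*T, p_1 = kappa_1*(T-1).
    With ``helpers=H``, the first binding recruits one of H helper molecules
    instead of a TF, so p_0 = kappa_0*H and p_1 = kappa_1*T.
    """
    _positive(kappa_0=kappa_0, kappa_minus1=kappa_minus1, kappa_minus2=kappa_minus2)
    if kappa_1 < 0:
        raise ValueError("kappa_1 must be non-negative")
    if helpers is None:
        if T < 2:
            raise ValueError("T must be >= 2 (fully bound state unreachable)")
        net = ReactionNetwork(
            ["F", "G0", "G1", "G2"],
            [
                Reaction((1, 1, 0, 0), (0, 0, 1, 0), kappa_0),
                Reaction((0, 0, 1, 0), (1, 1, 0, 0), kappa_minus1),
            ]
            + (
                [
                    Reaction((1, 0, 1, 0), (0, 0, 0, 1), kappa_1),
                    Reaction((0, 0, 0, 1), (1, 0, 1, 0), kappa_minus2),
                ]
                if kappa_1 > 0
                else []
            ),
        )
        states = [(T, 1, 0, 0), (T - 1, 0, 1, 0), (T - 2, 0, 0, 1)]
        p = [kappa_0 * T, kappa_1 * (T - 1)]
    else:
        if helpers < 1 or T < 1:
            raise ValueError("helpers >= 1 and T >= 1 required")
        net = ReactionNetwork(
            ["F", "H", "G0", "G1", "G2"],
            [
                Reaction((0, 1, 1, 0, 0), (0, 0, 0, 1, 0), kappa_0),
                Reaction((0, 0, 0, 1, 0), (0, 1, 1, 0, 0), kappa_minus1),
            ]
            + (
                [
                    Reaction((1, 0, 0, 1, 0), (0, 0, 0, 0, 1), kappa_1),
                    Reaction((0, 0, 0, 0, 1), (1, 0, 0, 1, 0), kappa_minus2),
                ]
                if kappa_1 > 0
                else []
            ),
        )
        states = [
            (T, helpers, 1, 0, 0),
            (T, helpers - 1, 0, 1, 0),
            (T - 1, helpers - 1, 0, 0, 1),
        ]
        p = [kappa_0 * helpers, kappa_1 * T]
    q = [kappa_minus1, kappa_minus2]
    if kappa_1 == 0:  # top state unreachable: restrict the path
        states, p, q = states[:2], p[:1], q[:1]
    space = StateSpace(states)
    dist = equilibrium_path(PathRates(tuple(p), tuple(q)))
    dist.space = space
    return MotifResult(
        dist, net, space,
        {
            "T": T,
            "kappa_0": kappa_0,
            "kappa_1": kappa_1,
            "kappa_minus1": kappa_minus1,
            "kappa_minus2": kappa_minus2,
            "helpers": helpers,
        },
    )


def independent_two_sites(
    T: int,
    kappa_0: float,
    kappa_1: float,
    kappa_minus1: float,
    kappa_minus2: float,
) -> MotifResult:
    """Gene with two sites bound in either order: four-state cycle
    (empty, site-A bound, site-B bound, both bound), with per-event rates
    kappa_0 (first binding, either site), kappa_1 (second binding),
    kappa_minus1 (unbinding from a singly bound gene), kappa_minus2
    (unbinding of either TF from the doubly bound gene).

    Under these symmetric per-site rates the cycle satisfies Kolmogorov's
    criterion, so the closed form is a detailed-balance product; the
    general cycle formula gives the same distribution (cross-checked in
    tests).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    _positive(
        kappa_0=kappa_0, kappa_1=kappa_1,
        kappa_minus1=kappa_minus1, kappa_minus2=kappa_minus2,
    )
    net = ReactionNetwork(
        ["F", "G00", "G10", "G01", "G11"],
        [
            Reaction((1, 1, 0, 0, 0), (0, 0, 1, 0, 0), kappa_0),
            Reaction((0, 0, 1, 0, 0), (1, 1, 0, 0, 0), kappa_minus1),
            Reaction((1, 1, 0, 0, 0), (0, 0, 0, 1, 0), kappa_0),
            Reaction((0, 0, 0, 1, 0), (1, 1, 0, 0, 0), kappa_minus1),
            Reaction((1, 0, 1, 0, 0), (0, 0, 0, 0, 1), kappa_1),
            Reaction((0, 0, 0, 0, 1), (1, 0, 1, 0, 0), kappa_minus2),
            Reaction((1, 0, 0, 1, 0), (0, 0, 0, 0, 1), kappa_1),
            Reaction((0, 0, 0, 0, 1), (1, 0, 0, 1, 0), kappa_minus2),
        ],
    )
    space = StateSpace(
        [
            (T, 1, 0, 0, 0),
            (T - 1, 0, 1, 0, 0),
            (T - 1, 0, 0, 1, 0),
            (T - 2, 0, 0, 0, 1),
        ]
    )
    w1 = kappa_0 * T / kappa_minus1
    w = np.array(
        [1.0, w1, w1, w1 * kappa_1 * (T - 1) / kappa_minus2]
    )
    dist = EquilibriumDistribution(w / w.sum(), space)
    return MotifResult(
        dist, net, space,
        {
            "T": T,
            "kappa_0": kappa_0,
            "kappa_1": kappa_1,
            "kappa_minus1": kappa_minus1,
            "kappa_minus2": kappa_minus2,
        },
    )


def independent_two_sites_cycle(
    T: int, kappa_0, kappa_1, kappa_minus1, kappa_minus2
) -> EquilibriumDistribution:
    """The same four-state distribution computed via the general circular
    formula (order: empty, A, A+B, B, mapped back to the motif's order)."""
    p = [kappa_0 * T, kappa_1 * (T - 1), kappa_minus2, kappa_minus1]
    q = [kappa_0 * T, kappa_minus1, kappa_minus2, kappa_1 * (T - 1)]
    cyc = equilibrium_cycle(p, q)
    reorder = [0, 1, 3, 2]  # cycle order (00, 10, 11, 01) -> (00, 10, 01, 11)
    return EquilibriumDistribution(cyc.probs[reorder])


def hypercube_compounded(
    N_sites: int,
    T: int,
    kappa_b: Optional[float] = None,
    kappa_u: Optional[float] = None,
    kappa_on: Optional[list] = None,
    kappa_off: Optional[list] = None,
) -> MotifResult:
    """N independent binding sites on one gene, compounded by occupancy.

    The compounded occupancy count i in {0..N} performs a path walk with
    p_i = kappa_on[i]*(N-i)*(T-i) and q_i = kappa_off[i]*i.  In the
    non-cooperative case (scalar kappa_b/kappa_u) this is exactly the
    tf_binding path over N gene copies, and that mass-action network is
    attached; the cooperative case carries the full hypercube rate matrix
    instead.
    """
    if not 1 <= N_sites <= T:
        raise ValueError("need 1 <= N_sites <= T")
    cooperative = kappa_on is not None or kappa_off is not None
    if cooperative:
        if kappa_on is None or kappa_off is None:
            raise ValueError("give both kappa_on and kappa_off for cooperativity")
        kon = [float(k) for k in kappa_on]
        koff = [float(k) for k in kappa_off]
        if len(kon) != N_sites or len(koff) != N_sites:
            raise ValueError("kappa_on/off need one entry per binding step")
    else:
        _positive(kappa_b=kappa_b, kappa_u=kappa_u)
        kon = [kappa_b] * N_sites
        koff = [kappa_u] * N_sites
    if any(k <= 0 for k in kon + koff):
        raise ValueError("all rate constants must be positive")
    p = [kon[i] * (N_sites - i) * (T - i) for i in range(N_sites)]
    q = [koff[i] * (i + 1) for i in range(N_sites)]
    dist = equilibrium_path(PathRates(tuple(p), tuple(q)))
    params = {"N_sites": N_sites, "T": T, "kappa_on": kon, "kappa_off": koff}
    if not cooperative:
        base = tf_binding(N_sites, T, kappa_b, kappa_u)
        dist.space = base.space
        return MotifResult(dist, base.network, base.space, params)
    Q = hypercube_rate_matrix(N_sites, T, kon, koff)
    return MotifResult(dist, None, None, params, rate_matrix=Q)


def hypercube_rate_matrix(N_sites, T, kappa_on, kappa_off) -> sp.csc_matrix:
    """Full Markov generator on the 2^N hypercube of site-occupancy vectors.

    From a vertex with i sites bound, each free site binds at
    kappa_on[i]*(T-i) and each bound site unbinds at kappa_off[i-1]... the
    occupancy-indexed constants are those of the compounded path: the total
    i -> i+1 rate is kappa_on[i]*(N-i)*(T-i) and i -> i-1 is kappa_off[i-1]*i.
    """
    n = 1 << N_sites
    Q = np.zeros((n, n))
    for v in range(n):
        i = bin(v).count("1")
        for s in range(N_sites):
            if not v & (1 << s):  # bind at free site s
                Q[v | (1 << s), v] += kappa_on[i] * (T - i)
            else:  # unbind occupied site s
                Q[v & ~(1 << s), v] += kappa_off[i - 1]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return sp.csc_matrix(Q)


def glued_three_site(
    T: int,
    variant: str = "path-cycle",
    kappa_0: float = 1.0,
    kappa_minus1: float = 1.0,
    kappa_1: float = 1.0,
    kappa_minus2: float = 1.0,
    kappa_2: float = 1.0,
    kappa_minus3: float = 1.0,
) -> MotifResult:
    """Gene with three non-overlapping TF binding sites, one of which is
    order-constrained; built by gluing a two-state chain and a four-state
    cycle at their shared state.

    variant="path-cycle": the unique site must bind the FIRST TF; states
    (empty, u, uA, uAB, uB) where u marks the unique site bound.
    variant="cycle-path": mirror image — the two unconstrained sites bind
    the first two TFs in either order, the unique site binds LAST; states
    (empty, A, B, AB, ABu).

    Rates: kappa_0/kappa_minus1 for the first binding layer,
    kappa_1/kappa_minus2 for the second, kappa_2/kappa_minus3 for the third;
    within a layer both sites share the same constants (the symmetric-rate
    assumption under which the cycle component has a closed form).
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    _positive(
        kappa_0=kappa_0, kappa_minus1=kappa_minus1, kappa_1=kappa_1,
        kappa_minus2=kappa_minus2, kappa_2=kappa_2, kappa_minus3=kappa_minus3,
    )
    from .solvers import glue_equilibria

    params = {
        "T": T, "variant": variant,
        "kappa_0": kappa_0, "kappa_minus1": kappa_minus1,
        "kappa_1": kappa_1, "kappa_minus2": kappa_minus2,
        "kappa_2": kappa_2, "kappa_minus3": kappa_minus3,
    }
    if variant == "path-cycle":
        # component 1: (empty, u); component 2: cycle (u, uA, uAB, uB)
        w1 = np.array([1.0, kappa_0 * T / kappa_minus1])
        a = kappa_1 * (T - 1) / kappa_minus2
        w2 = np.array([1.0, a, a * kappa_2 * (T - 2) / kappa_minus3, a])
        pi1 = EquilibriumDistribution(w1 / w1.sum())
        pi2 = EquilibriumDistribution(w2 / w2.sum())
        dist = glue_equilibria(pi1, pi2)
        net = ReactionNetwork(
            ["F", "Ge", "Gu", "GuA", "GuAB", "GuB"],
            [
                Reaction((1, 1, 0, 0, 0, 0), (0, 0, 1, 0, 0, 0), kappa_0),
                Reaction((0, 0, 1, 0, 0, 0), (1, 1, 0, 0, 0, 0), kappa_minus1),
                Reaction((1, 0, 1, 0, 0, 0), (0, 0, 0, 1, 0, 0), kappa_1),
                Reaction((0, 0, 0, 1, 0, 0), (1, 0, 1, 0, 0, 0), kappa_minus2),
                Reaction((1, 0, 1, 0, 0, 0), (0, 0, 0, 0, 0, 1), kappa_1),
                Reaction((0, 0, 0, 0, 0, 1), (1, 0, 1, 0, 0, 0), kappa_minus2),
                Reaction((1, 0, 0, 1, 0, 0), (0, 0, 0, 0, 1, 0), kappa_2),
                Reaction((0, 0, 0, 0, 1, 0), (1, 0, 0, 1, 0, 0), kappa_minus3),
                Reaction((1, 0, 0, 0, 0, 1), (0, 0, 0, 0, 1, 0), kappa_2),
                Reaction((0, 0, 0, 0, 1, 0), (1, 0, 0, 0, 0, 1), kappa_minus3),
            ],
        )
        states = [
            (T, 1, 0, 0, 0, 0),
            (T - 1, 0, 1, 0, 0, 0),
            (T - 2, 0, 0, 1, 0, 0),
            (T - 3, 0, 0, 0, 1, 0),
            (T - 2, 0, 0, 0, 0, 1),
        ]
    elif variant == "cycle-path":
        # component 1: cycle ordered (empty, A, B, AB); component 2: (AB, ABu)
        b = kappa_0 * T / kappa_minus1
        w1 = np.array([1.0, b, b, b * kappa_1 * (T - 1) / kappa_minus2])
        w2 = np.array([1.0, kappa_2 * (T - 2) / kappa_minus3])
        pi1 = EquilibriumDistribution(w1 / w1.sum())
        pi2 = EquilibriumDistribution(w2 / w2.sum())
        dist = glue_equilibria(pi1, pi2)
        net = ReactionNetwork(
            ["F", "Ge", "GA", "GB", "GAB", "GABu"],
            [
                Reaction((1, 1, 0, 0, 0, 0), (0, 0, 1, 0, 0, 0), kappa_0),
                Reaction((0, 0, 1, 0, 0, 0), (1, 1, 0, 0, 0, 0), kappa_minus1),
                Reaction((1, 1, 0, 0, 0, 0), (0, 0, 0, 1, 0, 0), kappa_0),
                Reaction((0, 0, 0, 1, 0, 0), (1, 1, 0, 0, 0, 0), kappa_minus1),
                Reaction((1, 0, 1, 0, 0, 0), (0, 0, 0, 0, 1, 0), kappa_1),
                Reaction((0, 0, 0, 0, 1, 0), (1, 0, 1, 0, 0, 0), kappa_minus2),
                Reaction((1, 0, 0, 1, 0, 0), (0, 0, 0, 0, 1, 0), kappa_1),
                Reaction((0, 0, 0, 0, 1, 0), (1, 0, 0, 1, 0, 0), kappa_minus2),
                Reaction((1, 0, 0, 0, 1, 0), (0, 0, 0, 0, 0, 1), kappa_2),
                Reaction((0, 0, 0, 0, 0, 1), (1, 0, 0, 0, 1, 0), kappa_minus3),
            ],
        )
        states = [
            (T, 1, 0, 0, 0, 0),
            (T - 1, 0, 1, 0, 0, 0),
            (T - 1, 0, 0, 1, 0, 0),
            (T - 2, 0, 0, 0, 1, 0),
            (T - 3, 0, 0, 0, 0, 1),
        ]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    space = StateSpace(states)
    dist.space = space
    return MotifResult(dist, net, space, params)
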