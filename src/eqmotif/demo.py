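"""Regulated-transcription demonstration: a single gene with fast TF
binding/unbinding and slow mRNA production and degradation.

The full model simulates all four species; the reduced model simulates the
mRNA count only, with the transcription propensity averaged over the
analytic Bernoulli binding equilibrium
Pr(bound) = kappa_b*T / (kappa_u + kappa_b*T), giving the effective rate
a_u*Pr(free) + a_b*Pr(bound).
"""

from __future__ import annotations

import numpy as np

from .network import Reaction, ReactionNetwork
from .qssa import SlowScaleModel

__all__ = [
    "regulated_transcription_full_network",
    "gene_tf_slow_model",
    "regulated_transcription_slow_model",
]


def regulated_transcription_full_network(
    T: int, kappa_b: float, kappa_u: float, a_u: float, a_b: float, kappa_d: float
) -> tuple[ReactionNetwork, tuple]:
    """Species (F, G, Gs, mRNA): fast G + F <-> Gs, slow transcription from
    either gene state and linear mRNA decay."""
    reactions = [
        Reaction((1, 1, 0, 0), (0, 0, 1, 0), kappa_b),
        Reaction((0, 0, 1, 0), (1, 1, 0, 0), kappa_u),
    ]
    if a_u > 0:
        reactions.append(Reaction((0, 1, 0, 0), (0, 1, 0, 1), a_u))
    if a_b > 0:
        reactions.append(Reaction((0, 0, 1, 0), (0, 0, 1, 1), a_b))
    reactions.append(Reaction((0, 0, 0, 1), (0, 0, 0, 0), kappa_d))
    net = ReactionNetwork(["F", "G", "Gs", "mRNA"], reactions)
    return net, (T, 1, 0, 0)


def gene_tf_slow_model(
    T: int, kappa_b: float, kappa_u: float, a_u: float, a_b: float, kappa_d: float
) -> SlowScaleModel:
    """Slow-scale model with the mRNA count as the only slow species; the
    fast gene/TF subsystem enters through its two-state equilibrium."""
    if T > 0:
        p_bound = kappa_b * T / (kappa_u + kappa_b * T)
    else:
        p_bound = 0.0
    fast_eq = np.array([1.0 - p_bound, p_bound])  # (free, bound)
    return SlowScaleModel(
        slow_species=["mRNA"],
        fast_equilibrium=lambda slow: fast_eq,
        slow_reactions=[
            ((1,), lambda slow: np.array([a_u, a_b])),
            ((-1,), lambda slow: np.array([kappa_d * slow[0], kappa_d * slow[0]])),
        ],
    )


def regulated_transcription_slow_model(
    net: ReactionNetwork, X0, a_u: float, a_b: float, kappa_d: float
) -> SlowScaleModel:
    """Build the reduced model from a parsed single-gene TF-binding network
    (reactions G + F -> Gs and Gs -> G + F, one gene copy in X0)."""
    kb = ku = None
    for r in net.reactions:
        if sum(r.reactants) == 2 and sum(r.products) == 1:
            kb = r.rate
            bound_idx = r.products.index(1)
            gene_idx, free_idx = sorted(
                i for i, v in enumerate(r.reactants) if v == 1
            )
        elif sum(r.reactants) == 1 and sum(r.products) == 2:
            ku = r.rate
    if kb is None or ku is None:
        raise ValueError("network is not a single-gene TF-binding system")
    gene_total = X0[gene_idx] + X0[bound_idx]
    # identify which bimolecular reactant is the gene: the one totalling 1
    T = X0[free_idx] + X0[bound_idx]
    if gene_total != 1:
        gene_total, T = T, gene_total
    if gene_total != 1:
        raise ValueError("demo requires exactly one gene copy")
    return gene_tf_slow_model(int(T), kb, ku, a_u, a_b, kappa_d)
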