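"""Seeded fixture generator: reproducible random networks and rate draws
for the test suites.

Rates are drawn log-uniformly from the spec's bounds with a Philox
generator keyed by the seed, so an identical FixtureSpec always yields an
identical fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Reaction, ReactionNetwork, StateSpace
from .solvers import PathRates

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "log_uniform"]

TOPOLOGIES = ("path", "cycle", "glued", "hypercube", "ladder", "random-motif")


@dataclass(frozen=True)
class FixtureSpec:
    topology: str
    size: int
    seed: int
    rate_lo: float = 1e-2
    rate_hi: float = 1e2

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 < self.rate_lo <= self.rate_hi:
            raise ValueError("need 0 < rate_lo <= rate_hi")


@dataclass
class Fixture:
    network: Optional[ReactionNetwork]
    space: Optional[StateSpace]
    X0: Optional[tuple]
    rates: dict = field(default_factory=dict)


def log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, 0xF1D0]))


def _one_hot_chain(n_states, transitions, rates):
    """First-order network over one-hot species C0..C{n-1}; ``transitions``
    are (from, to) index pairs with matching ``rates``."""
    species = [f"C{i}" for i in range(n_states)]
    reactions = []
    for (a, b), k in zip(transitions, rates):
        alpha = tuple(1 if i == a else 0 for i in range(n_states))
        beta = tuple(1 if i == b else 0 for i in range(n_states))
        reactions.append(Reaction(alpha, beta, float(k)))
    net = ReactionNetwork(species, reactions)
    states = [tuple(1 if i == j else 0 for i in range(n_states)) for j in range(n_states)]
    return net, StateSpace(states)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = _rng(spec.seed)
    lo, hi = spec.rate_lo, spec.rate_hi

    if spec.topology == "path":
        N = spec.size  # states 0..N
        p = log_uniform(rng, lo, hi, N)
        q = log_uniform(rng, lo, hi, N)
        trans = [(i, i + 1) for i in range(N)] + [(i + 1, i) for i in range(N)]
        net, space = _one_hot_chain(N + 1, trans, np.concatenate([p, q]))
        return Fixture(net, space, space.states[0],
                       {"path": PathRates(tuple(p), tuple(q))})

    if spec.topology == "cycle":
        N = spec.size
        if N < 3:
            raise ValueError("cycle needs size >= 3")
        p = log_uniform(rng, lo, hi, N)
        q = log_uniform(rng, lo, hi, N)
        trans = [(i, (i + 1) % N) for i in range(N)] + [(i, (i - 1) % N) for i in range(N)]
        net, space = _one_hot_chain(N, trans, np.concatenate([p, q]))
        return Fixture(net, space, space.states[0], {"forward": p, "backward": q})

    if spec.topology == "glued":
        # a path of `size` states glued (at its last state) to a cycle of
        # `size + 1` states; one-hot representation of the 2*size states
        r = spec.size
        s = spec.size + 1
        n = r + s - 1
        p1 = log_uniform(rng, lo, hi, r - 1)
        q1 = log_uniform(rng, lo, hi, r - 1)
        p2 = log_uniform(rng, lo, hi, s)
        q2 = log_uniform(rng, lo, hi, s)
        trans, rates = [], []
        for i in range(r - 1):  # the path part on states 0..r-1
            trans += [(i, i + 1), (i + 1, i)]
            rates += [p1[i], q1[i]]
        cyc = [r - 1] + list(range(r, n))  # cycle states, glued vertex first
        for i in range(s):
            a, b = cyc[i], cyc[(i + 1) % s]
            trans += [(a, b), (b, a)]
            rates += [p2[i], q2[(i + 1) % s]]
        net, space = _one_hot_chain(n, trans, rates)
        return Fixture(net, space, space.states[0], {
            "path": PathRates(tuple(p1), tuple(q1)),
            "cycle_forward": p2, "cycle_backward": q2, "r": r, "s": s,
        })

    if spec.topology == "hypercube":
        from .motifs import hypercube_compounded

        N = spec.size
        T = N + int(rng.integers(0, 3 * N + 1))
        kb, ku = log_uniform(rng, lo, hi, 2)
        res = hypercube_compounded(N, T, kb, ku)
        return Fixture(res.network, res.space, res.space.states[0],
                       {"N": N, "T": T, "kappa_b": kb, "kappa_u": ku})

    if spec.topology == "ladder":
        from .dimer_tf import dimer_tf_network

        T = spec.size
        k1, km1, kb, ku = log_uniform(rng, lo, hi, 4)
        net, space = dimer_tf_network(T, k1, km1, kb, ku)
        return Fixture(net, space, space.states[0], {
            "T": T, "kappa_1": k1, "kappa_minus1": km1,
            "kappa_b": kb, "kappa_u": ku,
        })

    if spec.topology == "random-motif":
        from . import motifs

        which = rng.integers(0, 5)
        k = log_uniform(rng, lo, hi, 6)
        n = spec.size
        if which == 0:
            res = motifs.isomerization(n, k[0], k[1])
        elif which == 1:
            res = motifs.tf_binding(max(1, n // 2), n, k[0], k[1])
        elif which == 2:
            res = motifs.dimerization(max(2, n), k[0], k[1])
        elif which == 3:
            res = motifs.sequential_two_sites(max(2, n), k[0], k[1], k[2], k[3])
        else:
            res = motifs.independent_two_sites(max(2, n), k[0], k[1], k[2], k[3])
        return Fixture(res.network, res.space, res.space.states[0],
                       dict(res.parameterization))

    raise ValueError(f"unknown topology {spec.topology!r}")
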