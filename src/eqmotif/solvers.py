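"""General-purpose equilibrium solvers for finite continuous-time Markov
chains: nullspace oracle, detailed-balance path formula, circular-chain
formula, spanning-tree (Kirchhoff / Markov chain tree theorem) method, and
the one-vertex gluing rule.

All solvers use the column-generator convention ``dP/dt = Q P``; an
equilibrium distribution is a normalized non-negative right nullvector of Q.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .network import StateSpace

__all__ = [
    "EquilibriumDistribution",
    "PathRates",
    "IllConditionedError",
    "TooLargeError",
    "equilibrium_nullspace",
    "equilibrium_oracle",
    "equilibrium_path",
    "equilibrium_cycle",
    "equilibrium_kirchhoff",
    "glue_equilibria",
    "detailed_balance_residual",
    "as_path_rates",
    "as_cycle_rates",
]


class IllConditionedError(RuntimeError):
    pass


class TooLargeError(RuntimeError):
    pass


@dataclass
class EquilibriumDistribution:
    """A probability vector over an ordered state space.

    ``space`` may be None for solvers that operate on abstract index sets
    (path / cycle formulas, gluing).
    """

    probs: np.ndarray
    space: Optional[StateSpace] = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size == 0:
            raise ValueError("probs must be a non-empty vector")
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        s = self.probs.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {s}")
        if self.space is not None and len(self.space) != self.probs.size:
            raise ValueError("distribution length must match the state space")

    def __len__(self):
        return self.probs.size

    def prob_of(self, state) -> float:
        return float(self.probs[self.space.index[tuple(state)]])


@dataclass(frozen=True)
class PathRates:
    """Birth-death rates on {0..N}: forward[i] is the i -> i+1 rate,
    backward[i] the i+1 -> i rate (i.e. q_{i+1}), both length N."""

    forward: tuple
    backward: tuple

    def __post_init__(self):
        if len(self.forward) != len(self.backward):
            raise ValueError("forward and backward must have equal length")
        if any(r <= 0 for r in self.forward + self.backward):
            raise ValueError("all path rates must be strictly positive")

    @property
    def n_states(self) -> int:
        return len(self.forward) + 1


def _closed_classes(Q: sp.spmatrix) -> list[np.ndarray]:
    """Closed communicating classes of the support digraph of Q.

    The support digraph has an edge from -> to whenever Q[to, from] > 0.
    A strongly connected component is closed iff no edge leaves it.
    """
    A = sp.csr_matrix(
        (np.abs(Q.data) > 0, Q.indices.copy(), Q.indptr.copy()), shape=Q.shape
    ) if sp.isspmatrix_csr(Q) else sp.csr_matrix(Q != 0)
    A.setdiag(0)
    A.eliminate_zeros()
    n, labels = csgraph.connected_components(A.T, directed=True, connection="strong")
    closed = []
    coo = A.tocoo()
    leaves = set()
    for frm, to in zip(coo.col, coo.row):  # A[to, frm] edge frm -> to
        if labels[frm] != labels[to]:
            leaves.add(labels[frm])
    for c in range(n):
        if c not in leaves:
            closed.append(np.flatnonzero(labels == c))
    return closed


def equilibrium_nullspace(Q: sp.spmatrix | np.ndarray) -> list[EquilibriumDistribution]:
    """Gaussian-elimination oracle: one equilibrium distribution per closed
    communicating class (supported on the full index set, zero elsewhere).

    Each class is solved by GTH elimination (Gaussian elimination
    specialized to generators; componentwise accurate), with an SVD
    fallback for degenerate input.
    """
    Q = sp.csr_matrix(Q)
    n = Q.shape[0]
    out = []
    for cls in _closed_classes(Q):
        sub = Q[np.ix_(cls, cls)].toarray()
        # restricted generator: recompute diagonal (class is closed, so the
        # original diagonal already matches, but be safe under truncation)
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, -sub.sum(axis=0))
        pi = _solve_single_class(sub)
        full = np.zeros(n)
        full[cls] = pi
        out.append(EquilibriumDistribution(full))
    return out


def _solve_single_class(Qc: np.ndarray) -> np.ndarray:
    """GTH (Grassmann-Taksar-Heyman) elimination on one irreducible class.

    Gaussian elimination specialized to generators: it uses only additions,
    multiplications and divisions of non-negative quantities, so the result
    is componentwise accurate even when the chain is badly conditioned
    (rate ratios of 1e4 and more occur in the seeded fixture suites).
    """
    m = Qc.shape[0]
    if m == 1:
        return np.ones(1)
    R = np.array(Qc, dtype=float).T  # R[i, j] = rate i -> j
    np.fill_diagonal(R, 0.0)
    svals = np.empty(m)
    for k in range(m - 1, 0, -1):
        s = R[k, :k].sum()
        if s <= 0 or not np.isfinite(s):
            raise IllConditionedError(
                "GTH elimination hit a zero pivot; class not irreducible?"
            )
        svals[k] = s
        R[:k, :k] += np.outer(R[:k, k], R[k, :k]) / s
    pi = np.zeros(m)
    pi[0] = 1.0
    for k in range(1, m):
        pi[k] = (pi[:k] @ R[:k, k]) / svals[k]
    total = pi.sum()
    if not np.isfinite(total) or total <= 0:
        pi = _svd_nullvector(Qc)
        pi = np.clip(pi, 0.0, None)
        total = pi.sum()
        if total <= 0:
            raise IllConditionedError("nullspace solve produced a zero vector")
    return pi / total


def _svd_nullvector(Qc: np.ndarray) -> np.ndarray:
    _, s, vt = np.linalg.svd(Qc)
    tol = max(Qc.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null_dim = int(np.sum(s <= tol))
    if null_dim > 1:
        cond = s[0] / s[-2] if s[-2] > 0 else np.inf
        raise IllConditionedError(
            f"rank-deficient beyond one nullvector (condition ~ {cond:.2e})"
        )
    v = vt[-1]
    if v.sum() < 0:
        v = -v
    return v


def equilibrium_oracle(Q) -> EquilibriumDistribution:
    """Convenience wrapper asserting a unique closed class."""
    dists = equilibrium_nullspace(Q)
    if len(dists) != 1:
        raise ValueError(f"expected one closed class, found {len(dists)}")
    return dists[0]


def equilibrium_path(rates: PathRates) -> EquilibriumDistribution:
    """Detailed-balance equilibrium on the path {0..N}:
    pi_i = pi_0 * prod_{k<i} p_k / q_{k+1}, with pi_0 obtained from the
    Horner-style right-to-left evaluation of the normalizing sum."""
    p = np.asarray(rates.forward, dtype=float)
    q = np.asarray(rates.backward, dtype=float)
    r = p / q  # r[i] = p_i / q_{i+1}
    # Horner: S = 1 + r0*(1 + r1*(1 + ... )) so that pi_0 = 1/S
    S = 1.0
    for ri in r[::-1]:
        S = 1.0 + ri * S
    n = r.size + 1
    pi = np.empty(n)
    pi[0] = 1.0 / S
    for i in range(1, n):
        pi[i] = pi[i - 1] * r[i - 1]
    return EquilibriumDistribution(pi / pi.sum())


def equilibrium_cycle(
    forward: Sequence[float], backward: Sequence[float]
) -> EquilibriumDistribution:
    """Equilibrium on the N-cycle {0..N-1} with forward[i] the i -> i+1 rate
    and backward[i] the i -> i-1 rate (indices mod N).

    Via the spanning trees of a cycle (cut one edge, direct the two arcs
    toward the root):
        pi_j  propto  sum_{m=0}^{N-1}  prod_{i=1}^{m} q_{j+i}
                                     * prod_{i=m+1}^{N-1} p_{j+i}
    with cyclic index interpretation (p_{i} = p_{i-N} for i >= N).
    """
    p = np.asarray(forward, dtype=float)
    q = np.asarray(backward, dtype=float)
    N = p.size
    if N < 3:
        raise ValueError("a cycle needs at least 3 states")
    if q.size != N:
        raise ValueError("forward and backward must have equal length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("all cycle rates must be strictly positive")
    w = np.empty(N)
    for j in range(N):
        total = 0.0
        for m in range(N):
            term = 1.0
            for i in range(1, m + 1):
                term *= q[(j + i) % N]
            for i in range(m + 1, N):
                term *= p[(j + i) % N]
            total += term
        w[j] = total
    return EquilibriumDistribution(w / w.sum())


def _count_spanning_trees(G) -> float:
    import networkx as nx

    L = nx.laplacian_matrix(G).toarray().astype(float)
    if L.shape[0] <= 1:
        return 1.0
    sign, logdet = np.linalg.slogdet(L[1:, 1:])
    return float(np.exp(logdet)) if sign > 0 else 0.0


def equilibrium_kirchhoff(
    Q: sp.spmatrix | np.ndarray, max_trees: float = 1e5, max_states: int = 12
) -> EquilibriumDistribution:
    """Markov chain tree theorem: weight(i) = sum over spanning trees of the
    undirected support graph of the product of intensities on edges directed
    toward i.  Zero-intensity directions contribute zero products."""
    import networkx as nx

    Qd = np.asarray(Q.toarray() if sp.issparse(Q) else Q, dtype=float)
    n = Qd.shape[0]
    if n > max_states:
        raise TooLargeError(f"{n} states exceeds the {max_states}-state guard")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            if Qd[a, b] > 0 or Qd[b, a] > 0:
                G.add_edge(a, b)
    comps = list(nx.connected_components(G))
    if len(comps) > 1:
        raise ValueError(
            "support graph disconnected; apply per component"
        )
    if _count_spanning_trees(G) > max_trees:
        raise TooLargeError("spanning tree count exceeds the guard")
    weights = np.zeros(n)
    for tree in nx.SpanningTreeIterator(G):
        for root in range(n):
            prod = 1.0
            # orient every tree edge toward root: child -> parent transitions
            for parent, child in nx.bfs_edges(tree, root):
                prod *= Qd[parent, child]  # rate child -> parent
                if prod == 0.0:
                    break
            weights[root] += prod
    s = weights.sum()
    if s <= 0:
        raise IllConditionedError("all spanning-tree weights vanished")
    return EquilibriumDistribution(weights / s)


def glue_equilibria(
    pi1: EquilibriumDistribution | Sequence[float],
    pi2: EquilibriumDistribution | Sequence[float],
) -> EquilibriumDistribution:
    """Equilibrium of the chain obtained by identifying the last state of
    process 1 with the first state of process 2 (all rates kept).

    Unnormalized weights: pi1_i * pi2_1 for the first chain (including the
    glued state, where it equals pi1_r * pi2_1) and pi1_r * pi2_j for the
    remainder of the second chain.
    """
    p1 = pi1.probs if isinstance(pi1, EquilibriumDistribution) else np.asarray(pi1, float)
    p2 = pi2.probs if isinstance(pi2, EquilibriumDistribution) else np.asarray(pi2, float)
    w = np.concatenate([p1 * p2[0], p1[-1] * p2[1:]])
    return EquilibriumDistribution(w / w.sum())


def as_path_rates(Q: sp.spmatrix | np.ndarray) -> tuple[list, PathRates]:
    """If the support graph of Q is a path, return the state order along it
    together with the corresponding PathRates; raise ValueError otherwise."""
    import networkx as nx

    Qd = np.asarray(Q.toarray() if sp.issparse(Q) else Q, dtype=float)
    n = Qd.shape[0]
    G = nx.Graph(
        (a, b) for a in range(n) for b in range(a + 1, n)
        if Qd[a, b] > 0 or Qd[b, a] > 0
    )
    G.add_nodes_from(range(n))
    if not nx.is_connected(G):
        raise ValueError("support graph is disconnected")
    degs = sorted(d for _, d in G.degree())
    if n == 1 or degs != [1, 1] + [2] * (n - 2):
        raise ValueError("support graph is not a path")
    ends = [v for v, d in G.degree() if d == 1]
    order = [min(ends)]
    prev = None
    while len(order) < n:
        nxt = next(v for v in G.neighbors(order[-1]) if v != prev)
        prev = order[-1]
        order.append(nxt)
    p = tuple(Qd[order[i + 1], order[i]] for i in range(n - 1))
    q = tuple(Qd[order[i], order[i + 1]] for i in range(n - 1))
    return order, PathRates(p, q)


def as_cycle_rates(Q: sp.spmatrix | np.ndarray) -> tuple[list, np.ndarray, np.ndarray]:
    """If the support graph of Q is a single cycle, return (state order,
    forward rates, backward rates) in the cycle convention."""
    import networkx as nx

    Qd = np.asarray(Q.toarray() if sp.issparse(Q) else Q, dtype=float)
    n = Qd.shape[0]
    G = nx.Graph(
        (a, b) for a in range(n) for b in range(a + 1, n)
        if Qd[a, b] > 0 or Qd[b, a] > 0
    )
    G.add_nodes_from(range(n))
    if n < 3 or not nx.is_connected(G) or any(d != 2 for _, d in G.degree()):
        raise ValueError("support graph is not a single cycle")
    order = [0]
    prev = None
    while len(order) < n:
        nxt = next(v for v in G.neighbors(order[-1]) if v != prev)
        prev = order[-1]
        order.append(nxt)
    p = np.array([Qd[order[(i + 1) % n], order[i]] for i in range(n)])
    q = np.array([Qd[order[i - 1], order[i]] for i in range(n)])
    return order, p, q


def detailed_balance_residual(
    Q: sp.spmatrix | np.ndarray, pi: EquilibriumDistribution | Sequence[float]
) -> float:
    """max over ordered state pairs of |q_{xy} pi_y - q_{yx} pi_x| where
    q_{xy} = Q[x, y] is the rate of the jump y -> x."""
    Qd = np.asarray(Q.toarray() if sp.issparse(Q) else Q, dtype=float)
    p = pi.probs if isinstance(pi, EquilibriumDistribution) else np.asarray(pi, float)
    flux = Qd * p[np.newaxis, :]  # flux[x, y] = q_{xy} pi_y
    np.fill_diagonal(flux, 0.0)
    return float(np.abs(flux - flux.T).max())
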