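"""Gillespie stochastic simulation (direct method), time-weighted occupancy
estimation, and slow-scale simulation with propensities averaged over an
analytic fast-subsystem equilibrium.

Randomness uses the counter-based Philox generator keyed by
(seed, stream id) for cross-platform reproducibility.  The time-scale
separation required for the quasi-steady-state averaging is NOT verified
here; the caller asserts it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .network import ReactionNetwork, propensity
from .solvers import EquilibriumDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "SlowScaleModel",
    "ssa_simulate",
    "empirical_distribution",
    "averaged_propensity",
    "slow_scale_ssa",
    "batch_means_sem",
    "time_average",
]


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, stream]))


@dataclass
class Trajectory:
    """Piecewise-constant jump path: state ``states[k]`` holds on
    [jump_times[k], jump_times[k+1]) and from the last jump to ``t_end``."""

    jump_times: np.ndarray
    states: np.ndarray  # (n_jumps, n_species), states[0] at jump_times[0]
    t_end: float
    species: list = field(default_factory=list)

    def __post_init__(self):
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int64)
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    @property
    def n_jumps(self):
        return len(self.jump_times)


def ssa_simulate(
    network: ReactionNetwork,
    X0: Sequence[int],
    t_end: float,
    seed: int,
    stream: int = 0,
    max_steps: int = 50_000_000,
) -> Trajectory:
    """Exact direct-method realization of the jump process on [0, t_end]."""
    rng = _rng(seed, stream)
    x = np.array(X0, dtype=np.int64)
    changes = np.array([r.change for r in network.reactions], dtype=np.int64)
    m = network.n_reactions
    times = [0.0]
    path = [x.copy()]
    t = 0.0
    a = np.empty(m)
    for _ in range(max_steps):
        for j in range(m):
            a[j] = propensity(network, j, x)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="left"))
        j = min(j, m - 1)
        x = x + changes[j]
        times.append(t)
        path.append(x.copy())
    else:
        raise RuntimeError(f"SSA exceeded max_steps={max_steps}")
    return Trajectory(np.array(times), np.array(path), t_end, list(network.species))


def empirical_distribution(
    traj: Trajectory, burn_in: float = 0.0
) -> EquilibriumDistribution:
    """Occupation-time-weighted distribution over visited states after
    ``burn_in``; returned on a StateSpace of the visited states in first-
    visit order."""
    from .network import StateSpace

    if traj.t_end <= burn_in:
        raise ValueError("t_end must exceed burn_in")
    times = np.append(traj.jump_times, traj.t_end)
    weights: dict = {}
    order: list = []
    for k in range(traj.n_jumps):
        lo = max(times[k], burn_in)
        hi = times[k + 1]
        if hi <= lo:
            continue
        s = tuple(int(v) for v in traj.states[k])
        if s not in weights:
            weights[s] = 0.0
            order.append(s)
        weights[s] += hi - lo
    total = sum(weights.values())
    space = StateSpace(order)
    probs = np.array([weights[s] / total for s in order])
    return EquilibriumDistribution(probs, space)


def averaged_propensity(
    fast_eq: EquilibriumDistribution | Sequence[float],
    slow_propensity_per_fast_state: Sequence[float],
) -> float:
    """Law of total expectation: sum_s pi_fast(s) * a(s)."""
    p = (
        fast_eq.probs
        if isinstance(fast_eq, EquilibriumDistribution)
        else np.asarray(fast_eq, dtype=float)
    )
    a = np.asarray(slow_propensity_per_fast_state, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    return float(p @ a)


@dataclass
class SlowScaleModel:
    """Slow dynamics with fast-subsystem averaging.

    fast_equilibrium(slow_state) must return the fast-subsystem equilibrium
    probabilities (a vector over fast states) given the slow state.
    Each slow reaction is (change vector over slow species, a(slow, fast)):
    the per-fast-state propensity vector returned by the second element is
    averaged under the fast equilibrium.  Averages are memoized per slow
    state.
    """

    slow_species: list
    fast_equilibrium: Callable[[tuple], np.ndarray]
    slow_reactions: list  # [(change: tuple, propensities: Callable[[tuple], np.ndarray])]

    def averaged_rates(self, slow_state: tuple, _cache: Optional[dict] = None):
        pi = np.asarray(self.fast_equilibrium(slow_state), dtype=float)
        if np.any(pi < -1e-12) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(
                f"fast-equilibrium provider returned an invalid distribution "
                f"at slow state {slow_state}"
            )
        return np.array(
            [averaged_propensity(pi, prop(slow_state)) for _, prop in self.slow_reactions]
        )


def slow_scale_ssa(
    model: SlowScaleModel,
    X0_slow: Sequence[int],
    t_end: float,
    seed: int,
    stream: int = 1,
    max_steps: int = 50_000_000,
) -> Trajectory:
    """SSA on the slow variables only, with every slow propensity replaced
    by its average under the fast-subsystem equilibrium conditioned on the
    current slow state."""
    rng = _rng(seed, stream)
    x = np.array(X0_slow, dtype=np.int64)
    changes = np.array([c for c, _ in model.slow_reactions], dtype=np.int64)
    m = len(model.slow_reactions)
    cache: dict = {}
    times = [0.0]
    path = [x.copy()]
    t = 0.0
    for _ in range(max_steps):
        key = tuple(int(v) for v in x)
        a = cache.get(key)
        if a is None:
            a = model.averaged_rates(key)
            cache[key] = a
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t >= t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="left"))
        j = min(j, m - 1)
        x = x + changes[j]
        times.append(t)
        path.append(x.copy())
    else:
        raise RuntimeError(f"slow-scale SSA exceeded max_steps={max_steps}")
    return Trajectory(np.array(times), np.array(path), t_end, list(model.slow_species))


def time_average(traj: Trajectory, species: int, burn_in: float = 0.0) -> float:
    """Time-weighted mean of one coordinate after burn_in."""
    times = np.append(traj.jump_times, traj.t_end)
    lo = np.maximum(times[:-1], burn_in)
    dt = np.clip(times[1:] - lo, 0.0, None)
    return float(np.sum(dt * traj.states[:, species]) / np.sum(dt))


def batch_means_sem(
    traj: Trajectory, species: int, burn_in: float = 0.0, n_batches: int = 20
) -> float:
    """Batch-means standard error of the time-averaged mean of one
    coordinate (20 batches by default), for autocorrelated occupancy
    estimates."""
    edges = np.linspace(burn_in, traj.t_end, n_batches + 1)
    times = np.append(traj.jump_times, traj.t_end)
    vals = traj.states[:, species].astype(float)
    means = np.empty(n_batches)
    for b in range(n_batches):
        lo = np.maximum(times[:-1], edges[b])
        hi = np.minimum(times[1:], edges[b + 1])
        dt = np.clip(hi - lo, 0.0, None)
        w = dt.sum()
        means[b] = np.sum(dt * vals) / w if w > 0 else np.nan
    means = means[np.isfinite(means)]
    k = means.size
    if k < 2:
        return float("inf")
    return float(means.std(ddof=1) / np.sqrt(k))
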