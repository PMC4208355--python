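import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import draw_rates
from eqmotif.fixtures import FixtureSpec, generate_fixture
from eqmotif.network import build_rate_matrix
from eqmotif.solvers import (
    EquilibriumDistribution,
    PathRates,
    TooLargeError,
    as_cycle_rates,
    as_path_rates,
    detailed_balance_residual,
    equilibrium_cycle,
    equilibrium_kirchhoff,
    equilibrium_nullspace,
    equilibrium_oracle,
    equilibrium_path,
    glue_equilibria,
)


def chain_Q(p, q):
    """Dense column-generator of a birth-death chain with given rates."""
    n = len(p) + 1
    Q = np.zeros((n, n))
    for i in range(n - 1):
        Q[i + 1, i] = p[i]
        Q[i, i + 1] = q[i]
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return Q


def cycle_Q(p, q):
    n = len(p)
    Q = np.zeros((n, n))
    for i in range(n):
        Q[(i + 1) % n, i] += p[i]
        Q[(i - 1) % n, i] += q[i]
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return Q


class TestNullspaceOracle:
    def test_symmetric_two_state(self):
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(equilibrium_oracle(Q).probs, [0.5, 0.5])

    def test_two_state_rates(self):
        Q = np.array([[-3.0, 5.0], [3.0, -5.0]])
        assert np.allclose(equilibrium_oracle(Q).probs, [5 / 8, 3 / 8])

    def test_uniform_four_cycle(self):
        Q = cycle_Q([1.0] * 4, [1.0] * 4)
        assert np.allclose(equilibrium_oracle(Q).probs, 0.25)

    def test_two_closed_classes(self):
        # two disconnected 2-state chains
        Q = np.zeros((4, 4))
        Q[1, 0] = Q[0, 1] = 1.0
        Q[3, 2] = 2.0
        Q[2, 3] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=0))
        dists = equilibrium_nullspace(sp.csr_matrix(Q))
        assert len(dists) == 2
        supports = sorted(tuple(np.flatnonzero(d.probs > 0)) for d in dists)
        assert supports == [(0, 1), (2, 3)]

    def test_transient_states_excluded(self):
        # 0 -> 1 <-> 2: state 0 is transient, closed class is {1, 2}
        Q = np.zeros((3, 3))
        Q[1, 0] = 1.0
        Q[2, 1] = 1.0
        Q[1, 2] = 3.0
        np.fill_diagonal(Q, -Q.sum(axis=0))
        dists = equilibrium_nullspace(sp.csr_matrix(Q))
        assert len(dists) == 1
        assert dists[0].probs[0] == 0.0
        assert np.allclose(dists[0].probs[1:], [0.75, 0.25])


class TestPathFormula:
    def test_symmetric_three_state(self):
        d = equilibrium_path(PathRates((1.0, 1.0), (1.0, 1.0)))
        assert np.allclose(d.probs, 1 / 3)

    def test_two_state(self):
        d = equilibrium_path(PathRates((2.0,), (1.0,)))
        assert np.allclose(d.probs, [1 / 3, 2 / 3])

    def test_matches_oracle_n20(self, rng):
        p, q = draw_rates(rng, 20), draw_rates(rng, 20)
        d = equilibrium_path(PathRates(tuple(p), tuple(q)))
        ref = equilibrium_oracle(chain_Q(p, q))
        assert np.abs(d.probs - ref.probs).max() < 1e-12

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            PathRates((1.0, 0.0), (1.0, 1.0))

    def test_long_path_stable(self, rng):
        # Horner normalization keeps 200-state paths finite and normalized
        p, q = draw_rates(rng, 200), draw_rates(rng, 200)
        d = equilibrium_path(PathRates(tuple(p), tuple(q)))
        assert np.isfinite(d.probs).all()
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_detailed_balance_by_construction(self, rng):
        p, q = draw_rates(rng, 10), draw_rates(rng, 10)
        d = equilibrium_path(PathRates(tuple(p), tuple(q)))
        assert detailed_balance_residual(chain_Q(p, q), d) < 1e-12


class TestCycleFormula:
    def test_uniform(self):
        d = equilibrium_cycle([2.0] * 5, [2.0] * 5)
        assert np.allclose(d.probs, 0.2)

    def test_matches_oracle(self, rng):
        for n in (3, 4, 7):
            p, q = draw_rates(rng, n), draw_rates(rng, n)
            d = equilibrium_cycle(p, q)
            ref = equilibrium_oracle(cycle_Q(p, q))
            assert np.abs(d.probs - ref.probs).max() < 1e-12

    def test_matches_kirchhoff_n3(self, rng):
        p, q = draw_rates(rng, 3), draw_rates(rng, 3)
        d = equilibrium_cycle(p, q)
        k = equilibrium_kirchhoff(cycle_Q(p, q))
        assert np.abs(d.probs - k.probs).max() < 1e-12

    def test_needs_three_states(self):
        with pytest.raises(ValueError):
            equilibrium_cycle([1.0, 1.0], [1.0, 1.0])


class TestKirchhoff:
    def test_single_edge(self):
        Q = np.array([[-3.0, 5.0], [3.0, -5.0]])
        assert np.allclose(equilibrium_kirchhoff(Q).probs, [5 / 8, 3 / 8])

    def test_three_cycle_uniform(self):
        d = equilibrium_kirchhoff(cycle_Q([1.0] * 3, [1.0] * 3))
        assert np.allclose(d.probs, 1 / 3)

    def test_guard(self):
        p = [1.0] * 13
        with pytest.raises(TooLargeError):
            equilibrium_kirchhoff(chain_Q(p, p))

    def test_four_cycle_vs_cycle_formula(self, rng):
        p, q = draw_rates(rng, 4), draw_rates(rng, 4)
        k = equilibrium_kirchhoff(cycle_Q(p, q))
        c = equilibrium_cycle(p, q)
        assert np.abs(k.probs - c.probs).max() < 1e-12

    def test_one_way_edges(self):
        # irreversible 3-cycle: trees directed against the flow contribute 0
        Q = np.zeros((3, 3))
        for i in range(3):
            Q[(i + 1) % 3, i] = 1.0 + i
        np.fill_diagonal(Q, -Q.sum(axis=0))
        k = equilibrium_kirchhoff(Q)
        ref = equilibrium_oracle(Q)
        assert np.abs(k.probs - ref.probs).max() < 1e-12


class TestGlue:
    def test_two_bernoullis_give_uniform(self):
        half = EquilibriumDistribution(np.array([0.5, 0.5]))
        d = glue_equilibria(half, half)
        assert np.allclose(d.probs, 1 / 3)

    def test_point_mass_identity(self, rng):
        w = rng.random(4) + 0.1
        p1 = EquilibriumDistribution(w / w.sum())
        point = EquilibriumDistribution(np.array([1.0]))
        d = glue_equilibria(p1, point)
        assert np.abs(d.probs - p1.probs).max() < 1e-15

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_of_glued_matrix(self, seed):
        fx = generate_fixture(FixtureSpec("glued", 4, seed=seed))
        Q = build_rate_matrix(fx.network, fx.space)
        ref = equilibrium_oracle(Q)
        p1 = equilibrium_path(fx.rates["path"])
        p2 = equilibrium_cycle(fx.rates["cycle_forward"], fx.rates["cycle_backward"])
        d = glue_equilibria(p1, p2)
        assert np.abs(d.probs - ref.probs).max() < 1e-12


class TestDetailedBalance:
    def test_cycle_breaking_kolmogorov(self):
        # forward product 2 != backward product 1 -> no detailed balance
        Q = cycle_Q([2.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        pi = equilibrium_oracle(Q)
        assert detailed_balance_residual(Q, pi) > 1e-3

    def test_zero_residual_implies_stationary(self, rng):
        p, q = draw_rates(rng, 6), draw_rates(rng, 6)
        Q = chain_Q(p, q)
        d = equilibrium_path(PathRates(tuple(p), tuple(q)))
        assert detailed_balance_residual(Q, d) < 1e-12
        assert np.abs(Q @ d.probs).max() < 1e-10


class TestChainDetection:
    def test_path_roundtrip(self, rng):
        p, q = draw_rates(rng, 5), draw_rates(rng, 5)
        Q = chain_Q(p, q)
        perm = rng.permutation(6)
        Qp = Q[np.ix_(perm, perm)]
        order, rates = as_path_rates(Qp)
        d = equilibrium_path(rates)
        probs = np.empty(6)
        probs[np.asarray(order)] = d.probs
        ref = equilibrium_oracle(Qp)
        assert np.abs(probs - ref.probs).max() < 1e-12

    def test_cycle_roundtrip(self, rng):
        p, q = draw_rates(rng, 5), draw_rates(rng, 5)
        Q = cycle_Q(p, q)
        order, pf, qf = as_cycle_rates(Q)
        d = equilibrium_cycle(pf, qf)
        probs = np.empty(5)
        probs[np.asarray(order)] = d.probs
        ref = equilibrium_oracle(Q)
        assert np.abs(probs - ref.probs).max() < 1e-12

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            as_path_rates(cycle_Q([1.0] * 4, [1.0] * 4))
        with pytest.raises(ValueError):
            as_cycle_rates(chain_Q([1.0] * 3, [1.0] * 3))


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=15),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_property_path_oracle_equivalence(n, seed):
    r = np.random.default_rng(seed)
    p = np.exp(r.uniform(-3, 3, n))
    q = np.exp(r.uniform(-3, 3, n))
    d = equilibrium_path(PathRates(tuple(p), tuple(q)))
    ref = equilibrium_oracle(chain_Q(p, q))
    assert np.abs(d.probs - ref.probs).max() < 1e-10


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(min_value=3, max_value=9),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_property_cycle_oracle_equivalence(n, seed):
    r = np.random.default_rng(seed)
    p = np.exp(r.uniform(-3, 3, n))
    q = np.exp(r.uniform(-3, 3, n))
    d = equilibrium_cycle(p, q)
    ref = equilibrium_oracle(cycle_Q(p, q))
    assert np.abs(d.probs - ref.probs).max() < 1e-10
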