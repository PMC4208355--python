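import numpy as np
import pytest

from conftest import draw_rates, oracle_of
from eqmotif.motifs import (
    birth_death,
    dimerization,
    glued_three_site,
    hypercube_compounded,
    hypercube_rate_matrix,
    independent_two_sites,
    independent_two_sites_cycle,
    isomerization,
    sequential_two_sites,
    single_gene_tf,
    tf_binding,
)
from eqmotif.solvers import detailed_balance_residual, equilibrium_oracle


class TestBirthDeath:
    def test_poisson_one(self):
        res = birth_death(1.0, 1.0)
        assert res.closed_form.probs[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_mode_pair_lambda_two(self):
        res = birth_death(2.0, 1.0)
        p = res.closed_form.probs
        assert p[1] == pytest.approx(p[2], rel=1e-12)
        assert p[1] == pytest.approx(2 * np.exp(-2.0), abs=1e-10)

    def test_truncated_vs_reflecting_oracle(self):
        eps = 1e-10
        res = birth_death(3.0, 1.0, eps=eps)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 10 * eps


class TestIsomerization:
    def test_symmetric_n2(self):
        res = isomerization(2, 1.0, 1.0)
        assert np.allclose(res.closed_form.probs, [0.25, 0.5, 0.25])

    def test_n1_is_bernoulli(self):
        res = isomerization(1, 3.0, 1.0)
        assert np.allclose(res.closed_form.probs, [0.25, 0.75])

    def test_goldbeter_koshland_rescaling(self):
        # enzyme counts enter only through effective first-order rates
        E1, E2 = 4, 6
        a = isomerization(5, 0.7 * E1, 0.3 * E2)
        b = isomerization(5, 0.7 * E1 * 10, 0.3 * E2 * 10)
        # ratio unchanged -> same binomial
        assert np.abs(a.closed_form.probs - b.closed_form.probs).max() < 1e-14

    @pytest.mark.parametrize("seed", range(5))
    def test_vs_oracle(self, seed):
        r = np.random.default_rng(seed)
        kp, km = draw_rates(r, 2)
        res = isomerization(6, kp, km)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12


class TestTfBinding:
    def test_n2_t3_recursion(self):
        # detailed-balance recursion gives unnormalized (1, 6, 6):
        # pi1 = 2*3 = 6, pi2 = pi1 * (1*2)/2 = 6; confirmed by the oracle
        res = tf_binding(2, 3, 1.0, 1.0)
        assert np.allclose(res.closed_form.probs, np.array([1, 6, 6]) / 13)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12

    def test_n1_reduces_to_single_gene(self):
        a = tf_binding(1, 7, 1.3, 0.9)
        b = single_gene_tf(7, 1.3, 0.9)
        assert np.abs(a.closed_form.probs - b.closed_form.probs).max() < 1e-14

    def test_swap_when_n_exceeds_t(self):
        a = tf_binding(5, 3, 1.0, 2.0)
        b = tf_binding(3, 5, 1.0, 2.0)
        assert np.abs(a.closed_form.probs - b.closed_form.probs).max() < 1e-14

    @pytest.mark.parametrize("seed", range(5))
    def test_vs_oracle(self, seed):
        r = np.random.default_rng(seed)
        kb, ku = draw_rates(r, 2)
        res = tf_binding(3, 8, kb, ku)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12


class TestDimerization:
    def test_total_two(self):
        res = dimerization(2, 1.0, 1.0)
        # p_0 = kappa_b*2*1 = 2, q_1 = kappa_u -> (1/3, 2/3)
        assert np.allclose(res.closed_form.probs, [1 / 3, 2 / 3])

    def test_odd_branch_vs_oracle(self):
        res = dimerization(5, 0.8, 1.7)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12

    def test_rejects_small_pool(self):
        with pytest.raises(ValueError):
            dimerization(1, 1.0, 1.0)

    def test_matches_conditional_product_form(self):
        from eqmotif.crnt import complex_balanced_state, product_form_equilibrium

        res = dimerization(9, 1.4, 0.6)
        c = complex_balanced_state(res.network)
        pf = product_form_equilibrium(res.network, c, res.space)
        assert np.abs(pf.probs - res.closed_form.probs).max() < 1e-12


class TestSingleGene:
    def test_t_zero(self):
        res = single_gene_tf(0, 1.0, 1.0)
        assert res.parameterization["p_bound"] == 0.0

    def test_balanced(self):
        res = single_gene_tf(4, 1.0, 4.0)  # kappa_b*T == kappa_u
        assert np.allclose(res.closed_form.probs, [0.5, 0.5])

    def test_hill_coefficient_one(self):
        # for f(T) = b*T/(u + b*T): f(2T)/f(T) = 2(u+bT)/(u+2bT), the
        # signature of a Hill curve with coefficient 1
        b, u, T = 1.3, 2.1, 5
        f = lambda t: single_gene_tf(t, b, u).parameterization["p_bound"]
        assert f(2 * T) / f(T) == pytest.approx(
            2 * (u + b * T) / (u + 2 * b * T), rel=1e-12
        )

    def test_monotone_in_t_and_affinity(self):
        ps = [single_gene_tf(T, 1.0, 3.0).parameterization["p_bound"]
              for T in range(1, 30)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        ps = [single_gene_tf(5, kb, 1.0).parameterization["p_bound"]
              for kb in np.linspace(0.1, 5, 20)]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestSequential:
    def test_all_ones_t2(self):
        res = sequential_two_sites(2, 1.0, 1.0, 1.0, 1.0)
        assert np.allclose(res.closed_form.probs, [0.2, 0.4, 0.4])

    def test_kappa1_zero_degenerate(self):
        res = sequential_two_sites(5, 1.0, 0.0, 1.0, 1.0)
        assert len(res.closed_form) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_vs_oracle(self, seed):
        r = np.random.default_rng(seed)
        k = draw_rates(r, 4)
        res = sequential_two_sites(6, *k)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_helper_variant_vs_oracle(self, seed):
        r = np.random.default_rng(100 + seed)
        k = draw_rates(r, 4)
        res = sequential_two_sites(4, *k, helpers=3)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12


class TestIndependent:
    def test_free_state_dominates_at_high_unbinding(self):
        res = independent_two_sites(5, 1.0, 1.0, 1e6, 1e6)
        assert res.closed_form.probs[0] > 0.999

    def test_closed_form_vs_cycle_formula(self, rng):
        k = draw_rates(rng, 4)
        a = independent_two_sites(6, *k).closed_form
        b = independent_two_sites_cycle(6, *k)
        assert np.abs(a.probs - b.probs).max() < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_vs_oracle(self, seed):
        r = np.random.default_rng(seed)
        k = draw_rates(r, 4)
        res = independent_two_sites(7, *k)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12

    def test_singly_bound_states_equal(self, rng):
        k = draw_rates(rng, 4)
        p = independent_two_sites(9, *k).closed_form.probs
        assert p[1] == pytest.approx(p[2], rel=1e-12)


def aggregate_hypercube(probs, n_sites):
    agg = np.zeros(n_sites + 1)
    for v in range(1 << n_sites):
        agg[bin(v).count("1")] += probs[v]
    return agg


class TestHypercube:
    def test_n2_t2_aggregation(self):
        res = hypercube_compounded(2, 2, 1.0, 1.0)
        Q = hypercube_rate_matrix(2, 2, [1.0, 1.0], [1.0, 1.0])
        ref = aggregate_hypercube(equilibrium_oracle(Q).probs, 2)
        assert np.abs(ref - res.closed_form.probs).max() < 1e-12

    def test_noncooperative_equals_tf_binding(self):
        a = hypercube_compounded(3, 7, 1.2, 0.8).closed_form
        b = tf_binding(3, 7, 1.2, 0.8).closed_form
        assert np.abs(a.probs - b.probs).max() < 1e-14

    def test_cooperative_vs_full_hypercube_oracle(self, rng):
        kon = draw_rates(rng, 3)
        koff = draw_rates(rng, 3)
        res = hypercube_compounded(3, 9, kappa_on=kon, kappa_off=koff)
        ref = aggregate_hypercube(equilibrium_oracle(res.rate_matrix).probs, 3)
        assert np.abs(ref - res.closed_form.probs).max() < 1e-12


class TestGluedThreeSite:
    @pytest.mark.parametrize("variant", ["path-cycle", "cycle-path"])
    @pytest.mark.parametrize("seed", range(5))
    def test_vs_oracle(self, variant, seed):
        r = np.random.default_rng(seed)
        k = draw_rates(r, 6)
        res = glued_three_site(6, variant, *k)
        ref = oracle_of(res)
        assert np.abs(ref.probs - res.closed_form.probs).max() < 1e-12

    def test_strong_unbinding_collapses_to_empty(self):
        res = glued_three_site(5, "path-cycle", kappa_minus1=1e6)
        assert res.closed_form.probs[0] > 0.999

    def test_rejects_small_t(self):
        with pytest.raises(ValueError):
            glued_three_site(2)


class TestDetailedBalanceAcrossMotifs:
    @pytest.mark.parametrize(
        "build",
        [
            lambda: isomerization(5, 1.3, 0.7),
            lambda: tf_binding(2, 6, 0.5, 2.0),
            lambda: dimerization(8, 1.1, 0.9),
            lambda: sequential_two_sites(5, 1.0, 2.0, 0.5, 1.5),
        ],
    )
    def test_path_motifs_satisfy_detailed_balance(self, build):
        res = build()
        Q = res.oracle_rate_matrix()
        assert detailed_balance_residual(Q, res.closed_form) < 1e-12

    def test_cycle_can_break_detailed_balance(self):
        # asymmetric per-site rates on the 4-cycle break Kolmogorov's
        # criterion; build the cycle generator directly
        from eqmotif.solvers import equilibrium_cycle

        p = [2.0, 1.0, 1.0, 1.0]
        q = [1.0, 1.0, 1.0, 1.0]
        n = 4
        Q = np.zeros((n, n))
        for i in range(n):
            Q[(i + 1) % n, i] += p[i]
            Q[(i - 1) % n, i] += q[i]
        np.fill_diagonal(Q, -Q.sum(axis=0))
        d = equilibrium_cycle(p, q)
        assert detailed_balance_residual(Q, d) > 1e-6
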