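"""Closed-form two-site exchange solution vs independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shutterspeed import twosite
from shutterspeed.twosite import (BiexpSolution, TwoSiteParams,
                                  effective_monoexp_r1, exchange_eigensystem,
                                  ffc_decay_signal, influx_from_efflux,
                                  ir_signal, kio_from_tau_ex,
                                  population_fractions, propagate_numeric)

from conftest import random_valid_params

valid_vex = st.floats(0.01, 0.99, exclude_min=True, exclude_max=True)
valid_rate = st.floats(1e-2, 1e3)


@pytest.mark.parametrize("v_ex, expected", [
    (0.5, (0.5, 0.5)),
    (0.2, (0.8, 0.2)),
    (0.15, (0.85, 0.15)),  # lower end of the tumor v_ex constraint range
])
def test_population_fractions(v_ex, expected):
    assert population_fractions(v_ex) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_population_fractions_domain(bad):
    with pytest.raises(ValueError):
        population_fractions(bad)


@pytest.mark.parametrize("k_io, v_ex, expected", [
    (2.0, 0.2, 8.0),
    (0.0, 0.3, 0.0),
    (5.0, 0.5, 5.0),
])
def test_influx_from_efflux(k_io, v_ex, expected):
    assert influx_from_efflux(k_io, v_ex) == pytest.approx(expected)


@pytest.mark.parametrize("tau_ex, v_ex, expected", [
    (1.0, 0.5, 1.0),
    (0.5, 0.2, 0.5),
])
def test_kio_from_tau_ex(tau_ex, v_ex, expected):
    assert kio_from_tau_ex(tau_ex, v_ex) == pytest.approx(expected)


def test_kio_from_tau_ex_rejects_nonpositive_lifetime():
    with pytest.raises(ValueError):
        kio_from_tau_ex(0.0, 0.3)


@settings(derandomize=True, max_examples=50)
@given(k_io=st.floats(1e-3, 1e3), v_ex=valid_vex)
def test_efflux_lifetime_round_trip(k_io, v_ex):
    """kio_from_tau_ex inverts influx_from_efflux exactly (mass balance)."""
    tau_ex = 1.0 / influx_from_efflux(k_io, v_ex)
    assert kio_from_tau_ex(tau_ex, v_ex) == pytest.approx(k_io, rel=1e-12)


class TestExchangeEigensystem:
    def test_no_exchange_limit(self):
        """Without exchange, apparent rates are the intrinsic rates and the
        amplitudes are the compartment populations."""
        sol = exchange_eigensystem(
            TwoSiteParams(r1_in=1.0, r1_ex=30.0, k_io=0.0, v_ex=0.2))
        assert sol.r1_fast == pytest.approx(30.0)
        assert sol.r1_slow == pytest.approx(1.0)
        assert sol.a_fast == pytest.approx(0.2)
        assert sol.a_slow == pytest.approx(0.8)

    def test_equal_rate_degeneracy_is_monoexponential(self):
        """Equal intrinsic rates: conservation forces a_fast = 0 and the
        observed recovery is monoexponential at the common rate."""
        sol = exchange_eigensystem(
            TwoSiteParams(r1_in=2.0, r1_ex=2.0, k_io=3.0, v_ex=0.3))
        assert sol.a_fast == 0.0
        assert sol.a_slow == 1.0
        assert sol.r1_slow == pytest.approx(2.0, rel=1e-12)

    def test_reference_parameter_set(self, derived_solution):
        """Frozen values verified against numerical eigen-decomposition of
        the exchange matrix and matrix-exponential propagation."""
        assert derived_solution.r1_fast == pytest.approx(
            38.45132307101624, rel=1e-12)
        assert derived_solution.r1_slow == pytest.approx(
            2.5486769289837596, rel=1e-12)
        assert derived_solution.a_fast == pytest.approx(
            0.11841252742758333, rel=1e-12)

    def test_rates_match_exchange_matrix_eigenvalues(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            params = random_valid_params(rng)
            sol = exchange_eigensystem(params)
            eig = np.sort(-np.linalg.eigvals(twosite.exchange_matrix(params)))
            assert sol.r1_slow == pytest.approx(eig[0], rel=1e-9)
            assert sol.r1_fast == pytest.approx(eig[1], rel=1e-9)


@settings(derandomize=True, max_examples=200)
@given(r1_in=valid_rate, r1_ex=valid_rate, k_io=st.floats(0, 1e3),
       v_ex=st.floats(0.05, 0.95))
def test_eigensolution_identities(r1_in, r1_ex, k_io, v_ex):
    """Conservation, trace and determinant identities of the closed form."""
    params = TwoSiteParams(r1_in=r1_in, r1_ex=r1_ex, k_io=k_io, v_ex=v_ex)
    sol = exchange_eigensystem(params)
    assert sol.r1_fast >= sol.r1_slow > 0
    assert sol.a_fast + sol.a_slow == pytest.approx(1.0, abs=1e-12)
    assert -1e-12 <= sol.a_fast <= 1 + 1e-12
    wbar = params.p_i * r1_in + params.p_o * r1_ex
    assert (sol.a_fast * sol.r1_fast + sol.a_slow * sol.r1_slow
            == pytest.approx(wbar, rel=1e-12))
    assert sol.r1_fast + sol.r1_slow == pytest.approx(
        r1_in + r1_ex + k_io + params.k_oi, rel=1e-12)
    assert sol.r1_fast * sol.r1_slow == pytest.approx(
        r1_in * r1_ex + r1_in * params.k_oi + r1_ex * k_io, rel=1e-12)


class TestSignals:
    def test_ir_perfect_inversion_at_zero(self, derived_solution):
        s = ir_signal([0.0, 1e-9, 50.0], derived_solution, m_inf=2.0,
                      inv_eff=1.0)
        assert s[0] == pytest.approx(-2.0)

    def test_ir_equilibrium_at_long_delay(self, derived_solution):
        tau = np.array([20.0 / derived_solution.r1_slow])
        s = ir_signal(tau, derived_solution, m_inf=3.0, inv_eff=0.9)
        assert s[0] == pytest.approx(3.0, rel=1e-8)

    def test_ir_matches_matrix_exponential(self, derived_solution):
        """Closed-form IR signal equals exact propagation of the initial
        deviation -2 m_inf (p_i, p_o) at every delay."""
        params = TwoSiteParams(r1_in=1.0, r1_ex=30.0, k_io=2.0, v_ex=0.2)
        tau = np.geomspace(1e-4, 10.0, 50)
        _, total_dev = propagate_numeric(
            params, [-2.0 * params.p_i, -2.0 * params.p_o], tau)
        expected = params.m_inf + total_dev
        got = ir_signal(tau, derived_solution, m_inf=1.0, inv_eff=1.0)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_ir_rejects_empty_grid_and_bad_inv_eff(self, derived_solution):
        with pytest.raises(ValueError):
            ir_signal([], derived_solution)
        with pytest.raises(ValueError):
            ir_signal([0.1], derived_solution, inv_eff=1.2)

    def test_ffc_constant_when_start_equals_equilibrium(self, derived_solution):
        s = ffc_decay_signal(np.linspace(0, 3, 10), derived_solution,
                             m_start=0.7, m_inf=0.7)
        np.testing.assert_allclose(s, 0.7)

    def test_np_buildup_endpoints(self, derived_solution):
        tau = np.array([0.0, 20.0 / derived_solution.r1_slow])
        s = ffc_decay_signal(tau, derived_solution, m_start=0.0, m_inf=1.5)
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert s[1] == pytest.approx(1.5, rel=1e-8)

    def test_pp_is_rescaled_ir_algebra(self, derived_solution):
        """A PP decay from 2 m_inf follows the same biexponential algebra
        as an inversion recovery: the initial deviation is +m_inf instead
        of -(1+inv_eff) m_inf, so PP = (3 m_inf - IR) / 2 pointwise."""
        tau = np.geomspace(1e-3, 4.0, 25)
        pp = ffc_decay_signal(tau, derived_solution, m_start=2.0, m_inf=1.0)
        ir = ir_signal(tau, derived_solution, m_inf=1.0, inv_eff=1.0)
        np.testing.assert_allclose(pp, (3.0 - ir) / 2.0, rtol=1e-12)


class TestEffectiveMonoexpR1:
    def test_pure_components_are_exact(self):
        tau = np.geomspace(0.01, 2.0, 16)
        slow_only = BiexpSolution(10.0, 2.0, 0.0, 1.0)
        fast_only = BiexpSolution(10.0, 2.0, 1.0, 0.0)
        assert effective_monoexp_r1(slow_only, tau) == pytest.approx(2.0)
        assert effective_monoexp_r1(fast_only, tau) == pytest.approx(10.0)

    def test_matches_brute_force_scan(self, derived_solution):
        """Bounded 1-D optimum agrees with a dense grid scan plus local
        parabolic refinement (independent oracle)."""
        tau = np.geomspace(0.001, 3.0, 32)
        sol = derived_solution
        f = (sol.a_fast * np.exp(-sol.r1_fast * tau)
             + sol.a_slow * np.exp(-sol.r1_slow * tau))

        def explained(r):
            g = np.exp(-r * tau)
            return (f @ g) ** 2 / (g @ g)

        grid = np.linspace(sol.r1_slow, sol.r1_fast, 20001)
        vals = np.array([explained(r) for r in grid])
        k = int(np.argmax(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
        fine = np.linspace(lo, hi, 2001)
        r_oracle = fine[int(np.argmax([explained(r) for r in fine]))]

        r_impl = effective_monoexp_r1(sol, tau)
        assert sol.r1_slow <= r_impl <= sol.r1_fast
        assert r_impl == pytest.approx(r_oracle, rel=1e-6)

    def test_monotone_in_k_io(self):
        """With r1_ex > r1_in, faster exchange pulls the observed rate up."""
        tau = np.geomspace(0.01, 3.0, 24)
        rates = []
        for k_io in [0.0, 0.5, 2.0, 8.0, 32.0]:
            sol = exchange_eigensystem(
                TwoSiteParams(r1_in=1.0, r1_ex=10.0, k_io=k_io, v_ex=0.3))
            rates.append(effective_monoexp_r1(sol, tau))
        assert np.all(np.diff(rates) >= -1e-10)

    def test_rejects_degenerate_grid(self, derived_solution):
        with pytest.raises(ValueError):
            effective_monoexp_r1(derived_solution, [0.1, 0.1, 0.1])


class TestPropagateNumeric:
    def test_no_exchange_independent_decays(self):
        params = TwoSiteParams(r1_in=1.0, r1_ex=5.0, k_io=0.0, v_ex=0.4)
        tau = np.array([0.0, 0.3, 1.0])
        comps, _ = propagate_numeric(params, [-1.2, -0.8], tau)
        np.testing.assert_allclose(comps[:, 0], -1.2 * np.exp(-1.0 * tau),
                                   rtol=1e-12)
        np.testing.assert_allclose(comps[:, 1], -0.8 * np.exp(-5.0 * tau),
                                   rtol=1e-12)

    def test_initial_slope_conserves_exchange_terms(self):
        """Exchange terms cancel in the total: the initial slope of the
        total deviation is -(p_i r1_in + p_o r1_ex) * 2 m_inf for full
        inversion."""
        params = TwoSiteParams(r1_in=1.0, r1_ex=30.0, k_io=7.0, v_ex=0.25)
        h = 1e-7
        d0 = np.array([-2.0 * params.p_i, -2.0 * params.p_o])
        _, total = propagate_numeric(params, d0, [0.0, h])
        slope = (total[1] - total[0]) / h
        expected = (params.p_i * params.r1_in
                    + params.p_o * params.r1_ex) * 2.0
        assert slope == pytest.approx(expected, rel=1e-5)

    def test_closed_form_equals_matrix_exponential_randomly(self):
        """The central oracle identity: closed-form biexponential total
        signal equals exact linear-system propagation."""
        rng = np.random.default_rng(202)
        tau = np.geomspace(1e-4, 30.0, 12)
        for _ in range(100):
            params = random_valid_params(rng)
            sol = exchange_eigensystem(params)
            d0 = np.array([-2.0 * params.p_i, -2.0 * params.p_o])
            _, total = propagate_numeric(params, d0, tau)
            closed = -2.0 * (sol.a_fast * np.exp(-sol.r1_fast * tau)
                             + sol.a_slow * np.exp(-sol.r1_slow * tau))
            np.testing.assert_allclose(closed, total, rtol=2e-9, atol=1e-13)

    def test_cross_check_against_fine_step_integrator(self):
        """Matrix exponential agrees with an explicit RK4 integration."""
        params = TwoSiteParams(r1_in=0.7, r1_ex=12.0, k_io=3.0, v_ex=0.2)
        a_mat = twosite.exchange_matrix(params)
        d = np.array([-1.6, -0.4])
        n_steps, t_end = 4000, 1.5
        h = t_end / n_steps
        for _ in range(n_steps):
            k1 = a_mat @ d
            k2 = a_mat @ (d + 0.5 * h * k1)
            k3 = a_mat @ (d + 0.5 * h * k2)
            k4 = a_mat @ (d + h * k3)
            d = d + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        comps, _ = propagate_numeric(params, [-1.6, -0.4], [t_end])
        np.testing.assert_allclose(comps[0], d, rtol=1e-9)


def test_fast_exchange_limit_monotone_convergence():
    """As k_io grows at fixed v_ex, a_fast -> 0 and r1_slow -> the
    population-weighted average rate, monotonically over 6 decades."""
    v_ex, r1_in, r1_ex = 0.3, 1.0, 20.0
    wbar = 0.7 * r1_in + 0.3 * r1_ex
    ladder = 10.0 ** np.arange(1, 7)
    a_fasts, gaps = [], []
    for k_io in ladder:
        sol = exchange_eigensystem(
            TwoSiteParams(r1_in=r1_in, r1_ex=r1_ex, k_io=k_io, v_ex=v_ex))
        a_fasts.append(sol.a_fast)
        gaps.append(abs(sol.r1_slow - wbar))
    assert np.all(np.diff(a_fasts) < 0)
    assert np.all(np.diff(gaps) < 0)
    assert a_fasts[-1] < 1e-5
    assert gaps[-1] < 1e-3 * wbar


@pytest.mark.parametrize("kwargs", [
    {"r1_in": -1.0, "r1_ex": 1.0, "k_io": 1.0, "v_ex": 0.5},
    {"r1_in": 1.0, "r1_ex": 0.0, "k_io": 1.0, "v_ex": 0.5},
    {"r1_in": 1.0, "r1_ex": 1.0, "k_io": -0.1, "v_ex": 0.5},
    {"r1_in": 1.0, "r1_ex": 1.0, "k_io": 1.0, "v_ex": 1.0},
])
def test_params_validation(kwargs):
    with pytest.raises(ValueError):
        TwoSiteParams(**kwargs)
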