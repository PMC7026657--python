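"""Four-state generator matrix, exact propagation, equilibria, relaxation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from quadkin import (
    RateConstants,
    equilibrium_populations,
    rate_matrix,
    slow_relaxation_time,
    solve_populations,
)

rates_st = st.builds(
    RateConstants,
    *[st.floats(1e-4, 1e3) for _ in range(5)],
)


class TestRateMatrix:
    def test_all_zero_rates_give_zero_matrix(self):
        assert np.all(rate_matrix(RateConstants(0, 0, 0, 0, 0)) == 0)

    def test_wt22m_row_diagonal_and_column_sums(self, wt22m_rates):
        m = rate_matrix(wt22m_rates)
        np.testing.assert_allclose(m.sum(axis=0), 0, atol=1e-14)
        np.testing.assert_allclose(np.diag(m), [-0.23, -0.037, -583.0, -2.7e-4])

    def test_single_edge(self):
        m = rate_matrix(RateConstants(1, 0, 0, 0, 0))
        expected = np.zeros((4, 4))
        expected[0, 0], expected[1, 0] = -1, 1
        np.testing.assert_array_equal(m, expected)

    def test_no_flow_back_into_hairpin(self, wt22m_rates):
        m = rate_matrix(wt22m_rates)
        assert np.all(m[0, 1:] == 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(-0.1, 1, 1, 1, 1)


class TestSolvePopulations:
    def test_frozen_system_static(self):
        traj = solve_populations(
            RateConstants(0, 0, 0, 0, 0), [0.3, 0.2, 0.1, 0.4], [1.0, 10.0, 100.0]
        )
        np.testing.assert_allclose(traj.states, [[0.3, 0.2, 0.1, 0.4]] * 3)

    def test_single_exponential_half_life(self):
        # With only the Hp -> G4(I) edge active the hairpin decays as a
        # pure exponential: at t = ln2/k1 exactly half has converted.
        traj = solve_populations(
            RateConstants(0.25, 0, 0, 0, 0), times=[np.log(2) / 0.25]
        )
        np.testing.assert_allclose(traj.states[0], [0.5, 0.5, 0, 0], atol=1e-12)

    def test_long_time_limit_matches_equilibrium(self, wt22m_rates):
        traj = solve_populations(wt22m_rates, times=[1e6])
        b, d, c = equilibrium_populations(wt22m_rates)
        np.testing.assert_allclose(traj.states[0], [0, b, d, c], atol=1e-6)
        assert traj.B[0] == pytest.approx(0.0722, abs=2e-4)
        assert traj.C[0] == pytest.approx(0.9278, abs=2e-4)

    def test_matches_stiff_ode_oracle_on_random_rates(self, rng):
        # Eigendecomposition route vs an adaptive stiff integrator on
        # log-uniform random rate sets spanning seven decades.
        times = np.geomspace(0.01, 1000, 40)
        worst = 0.0
        for _ in range(100):
            k = RateConstants(*10 ** rng.uniform(-4, 3, 5))
            traj = solve_populations(k, times=times)
            m = rate_matrix(k)
            sol = solve_ivp(
                lambda t, x: m @ x, (0, times[-1]), [1, 0, 0, 0],
                t_eval=times, method="LSODA", rtol=1e-11, atol=1e-13,
            )
            worst = max(worst, np.max(np.abs(traj.states - sol.y.T)))
        assert worst <= 1e-8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=rates_st)
    def test_conservation_and_nonnegativity(self, k):
        traj = solve_populations(k, times=np.geomspace(1e-3, 1e5, 60))
        np.testing.assert_allclose(traj.states.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(traj.states >= -1e-9)

    def test_irreversible_capture_is_monotone(self, wt22m_rates):
        # Without G4(II) unfolding (k5 = 0) the final state only accumulates.
        k = RateConstants(wt22m_rates.k1, wt22m_rates.k2, wt22m_rates.k3,
                          wt22m_rates.k4, 0.0)
        traj = solve_populations(k, times=np.linspace(0.1, 2000, 400))
        assert np.all(np.diff(traj.C) >= -1e-12)

    def test_g4i_is_transient_kinetic_product(self, wt22m_rates):
        # G4(I) overshoots far above its minor equilibrium share before the
        # slow conversion drains it into G4(II).
        traj = solve_populations(wt22m_rates, times=np.geomspace(0.1, 1e5, 500))
        b_eq = equilibrium_populations(wt22m_rates)[0]
        assert traj.B.max() > 5 * b_eq

    def test_negative_time_rejected(self, wt22m_rates):
        with pytest.raises(ValueError):
            solve_populations(wt22m_rates, times=[-1.0, 1.0])


class TestEquilibrium:
    def test_symmetric_branches_give_equal_quadruplex_fractions(self):
        b, d, c = equilibrium_populations(RateConstants(0, 100, 100, 1, 1))
        assert b == pytest.approx(c)

    def test_wt22m_minor_g4i_fraction(self, wt22m_rates):
        b, _, _ = equilibrium_populations(wt22m_rates)
        assert b == pytest.approx(0.0722, abs=1e-4)

    def test_5fc4_major_g4i_fraction(self, fc4_rates):
        b, _, _ = equilibrium_populations(fc4_rates)
        assert b == pytest.approx(0.884, abs=1e-3)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_populations(RateConstants(0.2, 10, 0, 1, 1))


class TestSlowRelaxation:
    def test_wt22m_interconversion_time(self, wt22m_rates):
        # NMR-observed G4(I) <-> G4(II) interconversion sits at 250 +/- 50 min.
        tau = slow_relaxation_time(wt22m_rates)
        assert tau == pytest.approx(292.4, abs=0.1)
        assert 200 <= tau <= 300

    def test_hand_checked_closed_form(self):
        # lam^2 - lam*(k2+k3+k4+k5) + (k4*k3 + k4*k5 + k2*k5) = 0; the slow
        # root is ~p/s = 40.0016/1000.08, i.e. tau ~ 25.0 min.
        tau = slow_relaxation_time(RateConstants(0, 500, 500, 0.04, 0.04))
        s_coef = 500 + 500 + 0.04 + 0.04
        p_coef = 0.04 * 500 + 0.04 * 0.04 + 500 * 0.04
        exact_slow = min(np.roots([1.0, -s_coef, p_coef]))
        assert tau == pytest.approx(1.0 / exact_slow, rel=1e-9)
        assert tau == pytest.approx(25.0, abs=0.01)

    def test_matches_numeric_eigensolver(self, rng):
        for _ in range(30):
            k = RateConstants(0, *10 ** rng.uniform(-3, 3, 4))
            sub = rate_matrix(k)[1:, 1:]
            lam = sorted(abs(v) for v in np.linalg.eigvals(sub))
            # smallest |eigenvalue| is the structural zero; next is the slow mode
            lam_slow = lam[1]
            assert slow_relaxation_time(k) == pytest.approx(1.0 / lam_slow, rel=1e-9)

    def test_no_unfolding_exchange_is_an_error(self):
        with pytest.raises(ValueError):
            slow_relaxation_time(RateConstants(0, 500, 50, 0, 0))
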