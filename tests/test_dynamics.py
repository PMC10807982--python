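"""Tests for integration, threshold crossing, and numerical equilibrium."""

import math

import numpy as np
import pytest

from cultsim import (
    DEFAULT_INITIAL,
    HorizonError,
    ModelParams,
    ParameterError,
    SimplexState,
    equilibrium_numeric,
    integrate,
    time_to_threshold,
)
from cultsim.reference import fixed_step_trajectory
from conftest import replace


class TestIntegrate:
    def test_no_turnover_run_fixes_the_efficient_solution(self, headline_params):
        """Without turnover there is no naive inflow: n stays 0, e rises
        monotonically to 1 and i goes extinct."""
        traj = integrate(replace(headline_params, m=0.0),
                         DEFAULT_INITIAL, 2000.0, 2001)
        assert np.all(np.abs(traj.n) < 1e-10)
        # tolerance covers solver round-off at the e = 1 plateau
        assert np.all(np.diff(traj.e) >= -1e-9)
        assert traj.final.e == pytest.approx(1.0, abs=1e-6)
        assert traj.final.i == pytest.approx(0.0, abs=1e-6)

    def test_all_naive_start_is_constant(self, headline_params):
        traj = integrate(headline_params, SimplexState(1, 0, 0), 100.0, 101)
        assert np.all(traj.states == [1.0, 0.0, 0.0])

    def test_simplex_preserved_along_trajectories(self, headline_params):
        for params in (headline_params,
                       replace(headline_params, m=0.3, c=0.2),
                       replace(headline_params, m=0.6)):
            traj = integrate(params, DEFAULT_INITIAL, 500.0, 501)
            assert traj.max_drift < 1e-7

    def test_matches_fixed_step_oracle(self, headline_params):
        """The adaptive solution must agree with blunt fixed-step schemes
        (forward Euler and classical RK4) written independently."""
        params = [headline_params, replace(headline_params, m=0.0, c=0.3)]
        initials = [DEFAULT_INITIAL, DEFAULT_INITIAL]
        times, rk4 = fixed_step_trajectory(params, initials, 100.0, 1e-3,
                                           "rk4", 101)
        _, euler = fixed_step_trajectory(params, initials, 100.0, 1e-4,
                                         "euler", 101)
        for b, p in enumerate(params):
            traj = integrate(p, DEFAULT_INITIAL, 100.0, 101)
            assert np.abs(traj.states - rk4[:, b, :]).max() < 1e-5
            assert np.abs(traj.states - euler[:, b, :]).max() < 1e-5

    def test_invalid_horizon_and_resolution(self, headline_params):
        with pytest.raises(ParameterError):
            integrate(headline_params, DEFAULT_INITIAL, 0.0)
        with pytest.raises(ParameterError):
            integrate(headline_params, DEFAULT_INITIAL, 10.0, resolution=1)


class TestTimeToThreshold:
    def test_turnover_accelerates_spread(self, headline_params):
        t_turn = time_to_threshold(headline_params, DEFAULT_INITIAL).t_h
        t_fixed = time_to_threshold(replace(headline_params, m=0.0),
                                    DEFAULT_INITIAL).t_h
        assert t_turn < t_fixed

    def test_threshold_already_met_is_zero(self, headline_params):
        res = time_to_threshold(headline_params, SimplexState(0.3, 0.2, 0.5),
                                threshold=0.5)
        assert res.reached and res.t_h == 0.0

    def test_unreachable_when_equilibrium_below_threshold(self, headline_params):
        # e* = 1 - 0.3/0.5 = 0.4 < 0.5: no finite crossing exists
        res = time_to_threshold(replace(headline_params, m=0.3),
                                DEFAULT_INITIAL, threshold=0.5)
        assert not res.reached and math.isinf(res.t_h)

    def test_small_horizon_raises_rather_than_misclassifies(self, headline_params):
        with pytest.raises(HorizonError):
            time_to_threshold(headline_params, DEFAULT_INITIAL, t_max=5.0)

    def test_auto_extend_recovers_from_small_horizon(self, headline_params):
        res = time_to_threshold(headline_params, DEFAULT_INITIAL, t_max=5.0,
                                auto_extend=True)
        ref = time_to_threshold(headline_params, DEFAULT_INITIAL)
        assert res.t_h == pytest.approx(ref.t_h, abs=1e-6)

    def test_trajectory_input_agrees_with_params_input(self, headline_params):
        traj = integrate(headline_params, DEFAULT_INITIAL, 100.0, 201)
        from_traj = time_to_threshold(traj)
        from_params = time_to_threshold(headline_params, DEFAULT_INITIAL)
        assert from_traj.t_h == pytest.approx(from_params.t_h, abs=1e-6)


class TestEquilibriumNumeric:
    def test_persistence_equilibrium_matches_closed_form(self, headline_params):
        eq = equilibrium_numeric(headline_params, DEFAULT_INITIAL)
        assert eq.e_star == pytest.approx(0.8, abs=1e-4)
        assert eq.state.i < 1e-4
        assert eq.regime == "persistence"
        assert eq.residual < 1e-9

    def test_strong_turnover_erodes_all_experience(self, headline_params):
        eq = equilibrium_numeric(replace(headline_params, m=0.6),
                                 DEFAULT_INITIAL)
        assert eq.state.n == pytest.approx(1.0, abs=1e-4)
        assert eq.regime == "extinction"

    def test_all_naive_start_returns_immediately(self, headline_params):
        eq = equilibrium_numeric(headline_params, SimplexState(1, 0, 0))
        assert eq.state == SimplexState(1, 0, 0)
        assert eq.regime == "degenerate_all_naive"
        assert eq.residual == 0.0

    def test_inefficient_solution_always_goes_extinct(self, headline_params):
        """With mu > 0 the inefficient compartment empties from any start
        that contains informed individuals."""
        for start in (DEFAULT_INITIAL, SimplexState(0.5, 0.25, 0.25),
                      SimplexState(0.0, 0.5, 0.5), SimplexState(0.98, 0.02, 0.0)):
            for params in (headline_params, replace(headline_params, m=0.3)):
                eq = equilibrium_numeric(params, start)
                assert eq.state.i < 1e-6
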