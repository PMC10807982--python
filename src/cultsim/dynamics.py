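"""Trajectory integration, time-to-threshold, and numerical equilibrium.

Integration uses an adaptive high-order Runge-Kutta method (DOP853) with
tight tolerances; the simplex constraint ``n + i + e = 1`` is *not* enforced
by renormalization — drift is asserted instead, so a solver defect cannot be
masked.  Threshold crossings are located by the solver's event machinery
(root-finding on the dense interpolant), giving crossing times far below the
1e-6 documented time tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import (
    DEGENERATE_ALL_NAIVE,
    EXTINCTION,
    PERSISTENCE,
    EquilibriumResult,
    equilibrium_analytic,
)
from .errors import HorizonError, IntegrationError, NonConvergenceError, ParameterError
from .model import ModelParams, SimplexState, rhs_terms

#: local error control for trajectory integration
RTOL = 1e-8
ATOL = 1e-10
#: allowed drift of n + i + e - 1 along a trajectory
DRIFT_TOL = 1e-7


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution of the compartment system.

    ``times`` is strictly increasing with ``times[0] = 0``; ``states`` has
    one row ``(n, i, e)`` per time point, each on the simplex up to solver
    drift (< 1e-7).  ``params`` may be ``None`` for trajectories read back
    from disk.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams | None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or y.shape != (t.size, 3):
            raise IntegrationError(
                f"inconsistent trajectory shapes: times {t.shape}, states {y.shape}"
            )
        if t.size and t[0] != 0.0:
            raise IntegrationError("trajectory must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise IntegrationError("trajectory times must be strictly increasing")
        drift = np.abs(y.sum(axis=1) - 1.0)
        if drift.size and drift.max() > DRIFT_TOL:
            raise IntegrationError(
                f"simplex drift {drift.max():.3g} exceeds {DRIFT_TOL:g}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def i(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def e(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def max_drift(self) -> float:
        return float(np.abs(self.states.sum(axis=1) - 1.0).max())

    def state(self, k: int) -> SimplexState:
        return SimplexState.from_array(self.states[k])

    @property
    def initial(self) -> SimplexState:
        return self.state(0)

    @property
    def final(self) -> SimplexState:
        return self.state(len(self) - 1)


@dataclass(frozen=True)
class ThresholdResult:
    """First-crossing time of the efficient fraction.

    ``t_h`` is ``math.inf`` when the threshold is never reached (the
    equilibrium efficient fraction lies at or below the threshold).
    """

    threshold: float
    t_h: float
    reached: bool


#: a crossing that never clears the threshold by this much is treated as
#: tangential grazing (the e* = threshold boundary), not a real crossing;
#: well above solver noise (~1e-7), far below any genuine transient
#: overshoot of the equilibrium
_TRANSVERSALITY_MARGIN = 1e-6


def _make_fun(params: ModelParams):
    mu, m, c, se, si = params.mu, params.m, params.c, params.se, params.si

    def fun(t, y):
        return rhs_terms(y[0], y[1], y[2], mu, m, c, se, si)

    return fun


def integrate(
    params: ModelParams,
    initial: SimplexState,
    t_max: float,
    resolution: int = 1001,
) -> Trajectory:
    """Solve the compartment ODEs on ``[0, t_max]``.

    Returns a :class:`Trajectory` sampled at ``resolution`` evenly spaced
    output points (the solver steps adaptively underneath; relative
    tolerance 1e-8, absolute 1e-10).
    """
    if not t_max > 0:
        raise ParameterError(f"t_max must be positive, got {t_max!r}")
    if resolution < 2:
        raise ParameterError(f"resolution must be >= 2, got {resolution!r}")
    t_eval = np.linspace(0.0, t_max, resolution)
    sol = solve_ivp(
        _make_fun(params), (0.0, t_max), initial.as_array(),
        method="DOP853", rtol=RTOL, atol=ATOL, t_eval=t_eval,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        last_y = sol.y[:, -1] if sol.t.size else initial.as_array()
        raise IntegrationError(
            f"solver failed at t = {last_t:g}: {sol.message}",
            t=float(last_t), last_state=last_y,
        )
    return Trajectory(sol.t, sol.y.T, params)


def time_to_threshold(
    source: Trajectory | ModelParams,
    initial: SimplexState | None = None,
    threshold: float = 0.5,
    t_max: float = 500.0,
    *,
    auto_extend: bool = False,
    horizon_cap: float = 1e7,
) -> ThresholdResult:
    """First time ``t_h`` at which the efficient fraction reaches ``threshold``.

    ``source`` may be a :class:`Trajectory` (its parameters and initial state
    are reused, with ``t_max`` taken as its final time) or a
    :class:`ModelParams` with an explicit ``initial`` state.

    If the threshold is not crossed by ``t_max``, the closed-form equilibrium
    decides the verdict: ``e* <= threshold`` means genuinely unreachable
    (``reached = False``, ``t_h = inf``); ``e* > threshold`` means the
    horizon was too small, which either extends the horizon (doubling up to
    ``horizon_cap`` when ``auto_extend`` is set) or raises
    :class:`~cultsim.errors.HorizonError`.

    A detected crossing with ``e* <= threshold`` is accepted only if the
    trajectory clears the threshold transversally (by at least 1e-6): at the
    boundary ``e* = threshold`` the trajectory grazes the threshold within
    solver noise without a well-posed finite crossing time, while genuine
    transient overshoots (possible when innovation is strong) clear it by a
    macroscopic margin.
    """
    if isinstance(source, Trajectory):
        if source.params is None:
            raise ParameterError(
                "trajectory has no attached parameters; pass ModelParams instead"
            )
        return time_to_threshold(
            source.params, source.initial, threshold,
            float(source.times[-1]), auto_extend=auto_extend,
            horizon_cap=horizon_cap,
        )
    params = source
    if initial is None:
        raise ParameterError("an initial state is required with ModelParams input")
    if threshold >= 1.0:
        raise ParameterError(f"threshold must be < 1, got {threshold!r}")
    if initial.e >= threshold:
        return ThresholdResult(threshold=threshold, t_h=0.0, reached=True)
    if not t_max > 0:
        raise ParameterError(f"t_max must be positive, got {t_max!r}")

    fun = _make_fun(params)

    def crossing(t, y):
        return y[2] - threshold

    crossing.terminal = True
    crossing.direction = 1.0

    t0, y0, horizon = 0.0, initial.as_array(), float(t_max)
    while True:
        sol = solve_ivp(
            fun, (t0, horizon), y0, method="DOP853",
            rtol=RTOL, atol=ATOL, events=crossing,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed locating threshold crossing: {sol.message}",
                t=float(sol.t[-1]), last_state=sol.y[:, -1],
            )
        if sol.t_events[0].size:
            t_hit = float(sol.t_events[0][0])
            try:
                e_star = equilibrium_analytic(params).e_star
            except ParameterError:
                e_star = None  # mu = 0: no closed form; trust the event
            if e_star is None or e_star > threshold:
                return ThresholdResult(
                    threshold=threshold, t_h=t_hit, reached=True
                )
            # equilibrium at or below the threshold yet an event fired:
            # genuine only if the trajectory clears the threshold by the
            # transversality margin afterwards
            def clears(t, y):
                return y[2] - (threshold + _TRANSVERSALITY_MARGIN)

            clears.terminal = True
            clears.direction = 1.0
            ver = solve_ivp(
                fun, (t_hit, max(horizon, t_hit + 0.5 * horizon)),
                sol.y_events[0][0], method="DOP853",
                rtol=RTOL, atol=ATOL, events=clears,
            )
            if ver.t_events[0].size:
                return ThresholdResult(
                    threshold=threshold, t_h=t_hit, reached=True
                )
            return ThresholdResult(
                threshold=threshold, t_h=math.inf, reached=False
            )
        e_star = equilibrium_analytic(params).e_star
        if e_star <= threshold:
            # approach is asymptotic from below (or stays below): no finite
            # crossing exists
            return ThresholdResult(threshold=threshold, t_h=math.inf, reached=False)
        if auto_extend and horizon < horizon_cap:
            t0, y0 = float(sol.t[-1]), sol.y[:, -1]
            horizon = min(2.0 * horizon, horizon_cap)
            continue
        raise HorizonError(
            f"threshold {threshold:g} is reachable (e* = {e_star:.6g}) but not "
            f"crossed by t_max = {horizon:g}; increase the horizon"
        )


#: long-horizon integration settings for equilibrium location
_EQ_RTOL = 1e-10
_EQ_ATOL = 1e-12
_OUTPUT_CLAMP = 1e-10


def equilibrium_numeric(
    params: ModelParams,
    initial: SimplexState,
    *,
    residual_tol: float = 1e-9,
    horizon_start: float = 1e3,
    horizon_cap: float = 1e7,
) -> EquilibriumResult:
    """Equilibrium by long-horizon integration with adaptive horizon doubling.

    Integrates from ``initial`` until ``max |rhs| < residual_tol`` at the
    endpoint, doubling the horizon from ``horizon_start`` up to
    ``horizon_cap``; raises :class:`~cultsim.errors.NonConvergenceError`
    (carrying the achieved residual) if the cap is hit first.  The all-naive
    start is an exact fixed point and is returned immediately.
    """
    if initial.i == 0.0 and initial.e == 0.0:
        return EquilibriumResult(
            state=initial, e_star=0.0, regime=DEGENERATE_ALL_NAIVE,
            residual=0.0, source="numeric", horizon=0.0,
        )
    fun = _make_fun(params)
    t_done, y = 0.0, initial.as_array()
    horizon = float(horizon_start)
    while True:
        sol = solve_ivp(
            fun, (t_done, horizon), y, method="LSODA",
            rtol=_EQ_RTOL, atol=_EQ_ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed during equilibrium search: {sol.message}",
                t=float(sol.t[-1]), last_state=sol.y[:, -1],
            )
        y = sol.y[:, -1]
        t_done = horizon
        residual = max(
            abs(d) for d in rhs_terms(
                y[0], y[1], y[2], params.mu, params.m, params.c,
                params.se, params.si,
            )
        )
        if residual < residual_tol:
            break
        if horizon >= horizon_cap:
            raise NonConvergenceError(
                f"no equilibrium within horizon {horizon_cap:g}: residual "
                f"{residual:.3g} >= {residual_tol:g}",
                residual=residual, state=y,
            )
        horizon = min(2.0 * horizon, horizon_cap)

    if abs(y.sum() - 1.0) > DRIFT_TOL:
        raise IntegrationError(
            f"simplex drift {abs(y.sum() - 1.0):.3g} at equilibrium endpoint"
        )
    # clamp solver-scale negative round-off at the output boundary only
    y = np.where((y < 0.0) & (y > -_OUTPUT_CLAMP), 0.0, y)
    state = SimplexState.from_array(y)
    # the m = se boundary decays algebraically and can satisfy the residual
    # tolerance while e is still ~1e-5; classify it with extinction, to which
    # it belongs by continuity of e* = 1 - m/se
    if state.e > 1e-4:
        regime = PERSISTENCE
    elif params.m > 0:
        regime = EXTINCTION
    else:
        regime = PERSISTENCE  # mu = 0, m = 0 continuum point: stays where it is
    return EquilibriumResult(
        state=state, e_star=state.e, regime=regime,
        residual=float(residual), source="numeric", horizon=t_done,
    )
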