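"""Closed-form equilibrium, regime classification, and robustness checks.

Because there is no cultural loss and innovation (``mu > 0``) keeps
converting inefficient individuals, the inefficient compartment always
empties in the long run.  What remains is a balance between turnover, which
injects naive individuals, and social learning from the efficient pool:

* persistence (``m < se``): the efficient fraction settles at
  ``e* = 1 - m / se``, with ``n* = m / se`` and ``i* = 0``;
* extinction (``m >= se``, ``m > 0``): naive newcomers arrive faster than
  they can learn, the pool of experience erodes, and the population ends up
  entirely naive (``e* = 0``);
* no turnover (``m = 0``): the efficient solution fixes, ``e* = 1``.

A direct corollary: the efficient solution can be held by half or more of
the population at equilibrium only when ``m <= se / 2``, i.e. when social
learning from efficient demonstrators runs at least twice as fast as
turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, RobustnessError
from .model import ModelParams, SimplexState, rhs

logger = logging.getLogger(__name__)

PERSISTENCE = "persistence"
EXTINCTION = "extinction"
DEGENERATE_ALL_NAIVE = "degenerate_all_naive"


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium state together with diagnostics.

    Attributes
    ----------
    state : SimplexState
        The equilibrium compartment fractions.
    e_star : float
        Efficient fraction at equilibrium (``state.e``).
    regime : str
        One of ``persistence``, ``extinction``, ``degenerate_all_naive``.
    residual : float
        ``max |rhs|`` at the returned state.
    source : str
        ``"analytic"`` (closed form) or ``"numeric"`` (long-horizon
        integration).
    horizon : float or None
        Integration horizon used (numeric source only).
    """

    state: SimplexState
    e_star: float
    regime: str
    residual: float
    source: str
    horizon: float | None = None


def _residual(state: SimplexState, params: ModelParams) -> float:
    return max(abs(d) for d in rhs(state, params))


def equilibrium_analytic(params: ModelParams) -> EquilibriumResult:
    """Closed-form equilibrium reached from any start with ``i0 + e0 > 0``.

    Requires ``mu > 0``: without innovation the system has a continuum of
    fixed points (any naive-free mixture is stationary when ``m = 0``) and no
    single equilibrium can be quoted, so ``mu = 0`` is rejected explicitly.
    """
    if params.mu <= 0:
        raise ParameterError(
            "equilibrium_analytic requires mu > 0: with mu = 0 the model has "
            "a continuum of fixed points and no unique equilibrium"
        )
    if params.m == 0:
        # no naive inflow: the efficient solution fixes (innovation alone
        # suffices even when se = 0)
        state = SimplexState(0.0, 0.0, 1.0)
        regime = PERSISTENCE
    elif params.m < params.se:
        n_star = params.m / params.se
        state = SimplexState(n_star, 0.0, 1.0 - n_star)
        regime = PERSISTENCE
    else:
        # m >= se (including se = 0): experience erodes faster than it
        # spreads; only naive individuals remain
        state = SimplexState(1.0, 0.0, 0.0)
        regime = EXTINCTION
    return EquilibriumResult(
        state=state,
        e_star=state.e,
        regime=regime,
        residual=_residual(state, params),
        source="analytic",
    )


@dataclass(frozen=True)
class RegimeReport:
    regime: str
    majority: bool
    e_star: float


def classify_regime(params: ModelParams) -> RegimeReport:
    """Regime label plus whether efficient individuals reach a majority.

    ``majority`` is true iff ``e* >= 1/2``, which for the closed form is
    exactly ``m <= se / 2`` (the boundary gives ``e* = 1/2`` and counts as a
    majority under "half or more").
    """
    res = equilibrium_analytic(params)
    majority = params.m <= params.se / 2.0
    return RegimeReport(regime=res.regime, majority=majority, e_star=res.e_star)


def sample_simplex_starts(
    n_starts: int,
    seed: int,
    min_informed: float = 0.01,
) -> list[SimplexState]:
    """Uniform (Dirichlet(1,1,1)) draws on the simplex, rejecting
    near-pure-naive points (``i0 + e0 < min_informed``)."""
    rng = np.random.default_rng(seed)
    starts: list[SimplexState] = []
    while len(starts) < n_starts:
        n0, i0, e0 = rng.dirichlet((1.0, 1.0, 1.0))
        if i0 + e0 >= min_informed:
            starts.append(SimplexState(float(n0), float(i0), float(e0)))
    return starts


@dataclass(frozen=True)
class RobustnessReport:
    starts: tuple[SimplexState, ...]
    e_values: np.ndarray
    max_spread: float
    max_error_vs_analytic: float
    e_star_analytic: float


def robustness_to_initial_conditions(
    params: ModelParams,
    n_starts: int = 20,
    seed: int = 0,
    *,
    min_informed: float = 0.01,
    tol: float = 1e-4,
) -> RobustnessReport:
    """Verify the equilibrium is independent of the starting condition.

    Draws ``n_starts`` uniform simplex points excluding the pure-naive
    vertex, integrates each to equilibrium, and checks that (a) the maximum
    pairwise spread of the efficient fraction is below ``tol`` and (b) each
    matches the closed form within ``tol``.  Raises
    :class:`~cultsim.errors.RobustnessError` on violation.

    The all-naive vertex is the one genuine exception: it is an (unstable to
    any informed perturbation, but exact) fixed point and is excluded by the
    ``min_informed`` rejection.
    """
    from .dynamics import equilibrium_numeric  # deferred: avoids import cycle

    if n_starts < 2:
        raise ParameterError("n_starts must be >= 2")
    if params.mu <= 0:
        raise ParameterError("robustness check requires mu > 0")
    starts = sample_simplex_starts(n_starts, seed, min_informed)
    e_values = np.array(
        [equilibrium_numeric(params, s).e_star for s in starts]
    )
    spread = float(e_values.max() - e_values.min())
    target = equilibrium_analytic(params).e_star
    max_err = float(np.abs(e_values - target).max())
    report = RobustnessReport(
        starts=tuple(starts),
        e_values=e_values,
        max_spread=spread,
        max_error_vs_analytic=max_err,
        e_star_analytic=target,
    )
    if spread > tol or max_err > tol:
        raise RobustnessError(
            f"equilibrium not robust to initial conditions: spread = "
            f"{spread:.3g}, max |e - e*_analytic| = {max_err:.3g} (tol {tol:g})"
        )
    return report
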