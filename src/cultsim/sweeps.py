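"""Parameter-space analyses: t_h and e* grids, the critical curve, and the
critical social-learning/turnover ratio.

The central object of interest is how the time ``t_h`` for the efficient
solution to reach half the population responds to turnover ``m``.  Above a
critical level of conservatism the response is negative — replacing
conservative veterans with eager naive learners speeds the spread — and
below it positive.  The locus in the ``(m, c)`` plane where the sensitivity
``d t_h / d m`` vanishes is the *critical curve*, located here by bisection
on a finite-difference sensitivity.

Independently of speed, turnover caps the equilibrium share of the
efficient solution at ``e* = 1 - m / se``; the ratio ``se / m`` at which
``e*`` crosses a target share is found by bisection on long-horizon
integrations (for a one-half share the ratio is 2: social learning must run
more than twice as fast as turnover for the trait to reach a majority).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import dynamics
from .equilibrium import equilibrium_analytic
from .errors import (
    CultsimError,
    NonConvergenceError,
    ParameterError,
    StencilError,
)
from .model import DEFAULT_INITIAL, ModelParams, SimplexState

logger = logging.getLogger(__name__)

#: default finite-difference step in m for t_h sensitivity — far below the
#: grid spacings one plots, far above the 1e-6 crossing-time tolerance
DEFAULT_DM = 1e-3


@dataclass(frozen=True)
class SweepGrid:
    """A rectangular parameter sweep with per-cell scalar results.

    ``values[j, k]`` corresponds to ``(axis1_values[j], axis2_values[k])``.
    Cells whose quantity does not exist (threshold unreachable, or numeric
    non-convergence) hold NaN in ``values`` and ``False`` in ``reachable``;
    the NaN is a placeholder paired with the mask, never data, and is
    serialized as an empty field.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    value_name: str
    values: np.ndarray
    reachable: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a1 = np.asarray(self.axis1_values, dtype=float)
        a2 = np.asarray(self.axis2_values, dtype=float)
        if a1.size == 0 or a2.size == 0:
            raise ParameterError("sweep axes must be non-empty")
        if np.any(np.diff(a1) <= 0) or np.any(np.diff(a2) <= 0):
            raise ParameterError("sweep axes must be strictly increasing")
        v = np.asarray(self.values, dtype=float)
        r = np.asarray(self.reachable, dtype=bool)
        if v.shape != (a1.size, a2.size) or r.shape != v.shape:
            raise ParameterError(
                f"cell arrays must have shape {(a1.size, a2.size)}"
            )
        object.__setattr__(self, "axis1_values", a1)
        object.__setattr__(self, "axis2_values", a2)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "reachable", r)

    def cell(self, j: int, k: int) -> tuple[float, bool]:
        return float(self.values[j, k]), bool(self.reachable[j, k])


def _params_from_fixed(fixed: dict, **overrides: float) -> ModelParams:
    merged = dict(fixed)
    merged.update(overrides)
    return ModelParams(**{k: float(merged[k]) for k in ("mu", "m", "c", "se", "si")})


def sweep_th(
    m_values,
    c_values,
    fixed: dict,
    initial: SimplexState = DEFAULT_INITIAL,
    threshold: float = 0.5,
    *,
    t_max: float = 500.0,
) -> SweepGrid:
    """Grid of ``t_h`` over turnover ``m`` (axis 1) and conservatism ``c``
    (axis 2); ``fixed`` supplies ``mu``, ``se`` and ``si``.

    Cells whose equilibrium efficient share never attains the threshold are
    marked unreachable.  Each cell is a pure function of its coordinates.
    """
    m_values = np.asarray(m_values, dtype=float)
    c_values = np.asarray(c_values, dtype=float)
    values = np.full((m_values.size, c_values.size), np.nan)
    reachable = np.zeros_like(values, dtype=bool)
    for j, m in enumerate(m_values):
        for k, c in enumerate(c_values):
            params = _params_from_fixed(fixed, m=m, c=c)
            try:
                res = dynamics.time_to_threshold(
                    params, initial, threshold, t_max, auto_extend=True
                )
            except CultsimError as exc:
                raise type(exc)(
                    f"sweep cell (m={m:g}, c={c:g}): {exc}"
                ) from exc
            if res.reached:
                values[j, k] = res.t_h
                reachable[j, k] = True
    return SweepGrid(
        axis1_name="m", axis1_values=m_values,
        axis2_name="c", axis2_values=c_values,
        value_name="t_h", values=values, reachable=reachable,
        fixed=dict(fixed),
    )


def sweep_estar(
    m_values,
    se_values,
    fixed: dict,
    mode: str = "analytic",
    initial: SimplexState = DEFAULT_INITIAL,
) -> SweepGrid:
    """Grid of the equilibrium efficient fraction ``e*`` over ``m`` (axis 1)
    and ``se`` (axis 2); ``fixed`` supplies ``mu``, ``c`` and ``si``.

    ``mode="analytic"`` evaluates the closed form; ``mode="numeric"``
    integrates to equilibrium from ``initial``.  Numeric non-convergence is
    recorded per cell (masked), not raised.
    """
    if mode not in ("analytic", "numeric"):
        raise ParameterError(f"mode must be 'analytic' or 'numeric', got {mode!r}")
    m_values = np.asarray(m_values, dtype=float)
    se_values = np.asarray(se_values, dtype=float)
    values = np.full((m_values.size, se_values.size), np.nan)
    reachable = np.zeros_like(values, dtype=bool)
    for j, m in enumerate(m_values):
        for k, se in enumerate(se_values):
            params = _params_from_fixed(fixed, m=m, se=se)
            if mode == "analytic":
                values[j, k] = equilibrium_analytic(params).e_star
                reachable[j, k] = True
            else:
                try:
                    values[j, k] = dynamics.equilibrium_numeric(
                        params, initial
                    ).e_star
                    reachable[j, k] = True
                except NonConvergenceError as exc:
                    logger.warning(
                        "cell (m=%g, se=%g) did not converge: %s", m, se, exc
                    )
    return SweepGrid(
        axis1_name="m", axis1_values=m_values,
        axis2_name="se", axis2_values=se_values,
        value_name="e_star", values=values, reachable=reachable,
        fixed=dict(fixed),
    )


def th_sensitivity(
    m: float,
    c: float,
    fixed: dict,
    threshold: float = 0.5,
    dm: float = DEFAULT_DM,
    initial: SimplexState = DEFAULT_INITIAL,
) -> float:
    """Finite-difference sensitivity of ``t_h`` to turnover at ``(m, c)``.

    Central difference ``(t_h(m+dm) - t_h(m-dm)) / (2 dm)``, falling back to
    a forward difference when ``m < dm``.  Negative means turnover
    accelerates the spread.  Raises :class:`~cultsim.errors.StencilError`
    if the threshold is unreachable at any stencil point.
    """

    def t_h_at(m_point: float) -> float:
        params = _params_from_fixed(fixed, m=m_point, c=c)
        res = dynamics.time_to_threshold(
            params, initial, threshold, auto_extend=True
        )
        if not res.reached:
            raise StencilError(
                f"threshold {threshold:g} unreachable at stencil point "
                f"m = {m_point:g} (c = {c:g})"
            )
        return res.t_h

    if m < dm:
        return (t_h_at(m + dm) - t_h_at(m)) / dm
    return (t_h_at(m + dm) - t_h_at(m - dm)) / (2.0 * dm)


@dataclass(frozen=True)
class CriticalCurve:
    """The locus c(m) where ``d t_h / d m = 0``.

    ``points`` has one ``(m, c)`` row per input m value for which the
    sensitivity changes sign on c in [0, 1]; m values without a sign change
    are listed in ``skipped_m``.
    """

    points: np.ndarray
    tolerance: float
    skipped_m: tuple[float, ...] = ()


def critical_curve(
    m_values,
    fixed: dict,
    threshold: float = 0.5,
    c_tolerance: float = 1e-4,
    *,
    scan_points: int = 11,
    initial: SimplexState = DEFAULT_INITIAL,
) -> CriticalCurve:
    """Locate, for each m, the conservatism c at which turnover neither
    accelerates nor slows the spread.

    A coarse scan over ``scan_points`` c values brackets sign changes of
    :func:`th_sensitivity`; the bracket whose midpoint is nearest the
    previous m's root (for curve continuity) is refined by bisection until
    its width is below ``c_tolerance / 2``, so the returned c is within
    ``c_tolerance`` of the true root regardless of the initial bracketing.
    m values without a sign change are omitted and logged.
    """
    m_values = np.asarray(m_values, dtype=float)
    points: list[tuple[float, float]] = []
    skipped: list[float] = []
    prev_root: float | None = None
    for m in m_values:
        c_scan = np.linspace(0.0, 1.0, scan_points)
        try:
            sens = np.array([
                th_sensitivity(m, cv, fixed, threshold, initial=initial)
                for cv in c_scan
            ])
        except StencilError as exc:
            logger.info("m = %g skipped (unreachable): %s", m, exc)
            skipped.append(float(m))
            continue
        sign = np.sign(sens)
        brackets = [
            (c_scan[j], c_scan[j + 1], sens[j], sens[j + 1])
            for j in range(c_scan.size - 1)
            if sign[j] != sign[j + 1] and sign[j] != 0
        ]
        if not brackets:
            logger.info("m = %g: no sign change of dt_h/dm on c in [0, 1]", m)
            skipped.append(float(m))
            continue
        if len(brackets) > 1:
            logger.warning(
                "m = %g: %d sign changes in c; keeping the root nearest the "
                "previous one", m, len(brackets),
            )
        anchor = prev_root if prev_root is not None else None
        if anchor is None:
            lo, hi, s_lo, _ = brackets[0]
        else:
            lo, hi, s_lo, _ = min(
                brackets, key=lambda b: abs(0.5 * (b[0] + b[1]) - anchor)
            )
        while hi - lo > c_tolerance / 2.0:
            mid = 0.5 * (lo + hi)
            s_mid = th_sensitivity(m, mid, fixed, threshold, initial=initial)
            if s_mid == 0.0:
                lo = hi = mid
            elif math.copysign(1.0, s_mid) == math.copysign(1.0, s_lo):
                lo, s_lo = mid, s_mid
            else:
                hi = mid
        root = 0.5 * (lo + hi)
        points.append((float(m), float(root)))
        prev_root = root
    return CriticalCurve(
        points=np.array(points).reshape(-1, 2),
        tolerance=c_tolerance,
        skipped_m=tuple(skipped),
    )


def critical_ratio(
    fixed: dict,
    se: float,
    threshold: float = 0.5,
    initial: SimplexState = DEFAULT_INITIAL,
) -> float:
    """Ratio ``se / m`` at which the equilibrium efficient share equals
    ``threshold``, found by root-finding on long-horizon integrations.

    ``fixed`` supplies ``mu``, ``c`` and ``si``.  For a one-half threshold
    the ratio is 2 — social learning must outpace turnover at least twofold
    for the efficient solution to reach a majority (closed form:
    ``1 / (1 - threshold)``, against which the numerical root is logged).
    """
    if not se > 0:
        raise ParameterError("critical_ratio requires se > 0")
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold!r}")

    def excess(m: float) -> float:
        params = _params_from_fixed(fixed, m=m, se=se)
        return dynamics.equilibrium_numeric(params, initial).e_star - threshold

    m_guess = (1.0 - threshold) * se
    lo = 0.5 * m_guess
    hi = 0.5 * (m_guess + se)
    m_root = brentq(excess, lo, hi, xtol=1e-8, rtol=1e-12)
    ratio = se / m_root
    logger.debug(
        "critical ratio %.8g (closed form %.8g)", ratio, 1.0 / (1.0 - threshold)
    )
    return float(ratio)
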