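"""Core model definition: parameters, state, and the vector field.

The population facing a two-solution problem is split into three fractions:
naive individuals ``n`` (know neither solution), inefficient individuals
``i`` (use the worse solution), and efficient individuals ``e`` (use the
better one), with ``n + i + e = 1`` at all times.  Three processes move mass
between compartments in continuous time:

* innovation — inefficient individuals independently discover the efficient
  solution at per-capita rate ``mu``;
* turnover — individuals of every compartment are replaced by naive
  newcomers at per-capita rate ``m`` (migration or birth-death);
* social learning — pairwise mass-action encounters at the product of
  compartment frequencies.  Naive individuals always attempt to learn;
  knowledgeable individuals are behaviorally conservative and attempt only
  with probability ``1 - c``.  Attempts on an efficient (inefficient)
  demonstrator succeed at rate ``se`` (``si``).

There is no cultural loss: an efficient individual can revert to the
inefficient solution only through social learning, never spontaneously.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SimplexError

logger = logging.getLogger(__name__)

PARAM_FIELDS = ("mu", "m", "c", "se", "si")

#: slack allowed on individual fractions for solver round-off
_COMPONENT_SLACK = 1e-12
#: tolerance on n + i + e = 1 at construction
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """The five rate/probability parameters of the model.

    Parameters
    ----------
    mu : float
        Innovation rate per unit time (``mu >= 0``).
    m : float
        Population turnover rate per unit time (``m >= 0``).
    c : float
        Behavioral conservatism: probability that a knowledgeable individual
        ignores a social-learning opportunity (``0 <= c <= 1``).
    se : float
        Success rate of a learning attempt on an efficient demonstrator.
    si : float
        Success rate of a learning attempt on an inefficient demonstrator.

    The model's standing assumption is ``se > si`` (the efficient solution is
    the more attractive one once encountered).  Violating it is allowed — the
    boundary ``se = si`` is useful for symmetry checks — but logged as a
    warning by :func:`check_learnability_ordering`.
    """

    mu: float
    m: float
    c: float
    se: float
    si: float

    def __post_init__(self) -> None:
        for name in ("mu", "m", "se", "si"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)) or v < 0:
                raise ParameterError(
                    f"parameter {name!r} must be a finite non-negative rate, got {v!r}"
                )
        if not (isinstance(self.c, (int, float)) and math.isfinite(self.c)
                and 0.0 <= self.c <= 1.0):
            raise ParameterError(
                f"parameter 'c' must lie in [0, 1], got {self.c!r}"
            )

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_FIELDS}


def check_learnability_ordering(params: ModelParams) -> bool:
    """Return True iff ``se > si``; log a warning otherwise.

    This is the model's standing assumption ("efficient individuals attract
    more learners"); it is deliberately a warning rather than a hard error so
    the boundary can be probed.
    """
    ok = params.se > params.si
    if not ok:
        logger.warning(
            "se = %g <= si = %g: the efficient solution is not the more "
            "attractive one; results outside the model's standing assumption",
            params.se, params.si,
        )
    return ok


def validate_params(raw: Mapping[str, float]) -> ModelParams:
    """Validate a name -> value mapping into a :class:`ModelParams`.

    All five of ``mu, m, c, se, si`` must be present; unknown keys are
    rejected.  ``se <= si`` triggers a logged warning, not an error.
    """
    unknown = sorted(set(raw) - set(PARAM_FIELDS))
    if unknown:
        raise ParameterError(
            f"unknown parameter(s) {unknown}; valid names are {list(PARAM_FIELDS)}"
        )
    missing = sorted(set(PARAM_FIELDS) - set(raw))
    if missing:
        raise ParameterError(f"missing parameter(s) {missing}")
    params = ModelParams(**{k: float(raw[k]) for k in PARAM_FIELDS})
    check_learnability_ordering(params)
    return params


@dataclass(frozen=True)
class SimplexState:
    """Compartment fractions ``(n, i, e)`` on the 2-simplex.

    Direct construction tolerates tiny negative round-off (1e-12) from ODE
    solvers; user-supplied fractions should go through
    :meth:`from_fractions`, which requires each component in [0, 1] exactly.
    """

    n: float
    i: float
    e: float

    def __post_init__(self) -> None:
        for name in ("n", "i", "e"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise SimplexError(f"fraction {name!r} must be finite, got {v!r}")
            if v < -_COMPONENT_SLACK or v > 1.0 + _COMPONENT_SLACK:
                raise SimplexError(
                    f"fraction {name!r} = {v!r} outside [0, 1] "
                    f"(slack {_COMPONENT_SLACK:g})"
                )
        total = self.n + self.i + self.e
        if abs(total - 1.0) > _SUM_TOL:
            raise SimplexError(
                f"fractions must sum to 1 within {_SUM_TOL:g}; "
                f"got n + i + e = {total!r}"
            )

    @classmethod
    def from_fractions(cls, n: float, i: float, e: float) -> "SimplexState":
        """Strict constructor for user input: each fraction in [0, 1] exactly."""
        for name, v in (("n", n), ("i", i), ("e", e)):
            if not (0.0 <= v <= 1.0):
                raise SimplexError(
                    f"fraction {name!r} = {v!r} must lie in [0, 1]"
                )
        return cls(float(n), float(i), float(e))

    @classmethod
    def from_array(cls, y) -> "SimplexState":
        return cls(float(y[0]), float(y[1]), float(y[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.i, self.e], dtype=float)


#: canonical starting condition: a population of inefficient individuals
DEFAULT_INITIAL = SimplexState(0.0, 1.0, 0.0)


def rhs_terms(n, i, e, mu, m, c, se, si):
    """Vector field of the model evaluated on raw numbers (or arrays).

    Returns ``(dn, di, de)``.  Scalar or vectorized; no validation.
    """
    learn_e = n * e * se          # naive learns from efficient
    learn_i = n * i * si          # naive learns from inefficient
    open_pair = (1.0 - c) * i * e  # non-conservative knowledgeable encounters
    ex_ie = open_pair * se        # inefficient switches to efficient
    ex_ei = open_pair * si        # efficient switches to inefficient
    dn = m * i + m * e - learn_e - learn_i
    di = -mu * i - m * i + learn_i + ex_ei - ex_ie
    de = mu * i - m * e + learn_e - ex_ei + ex_ie
    return dn, di, de


def rhs(state: SimplexState, params: ModelParams) -> tuple[float, float, float]:
    """Time derivatives ``(dn/dt, di/dt, de/dt)`` at ``state``.

    The three derivatives sum to zero up to floating round-off (the
    population is closed).
    """
    return rhs_terms(state.n, state.i, state.e,
                     params.mu, params.m, params.c, params.se, params.si)


#: per-process flows; each maps name -> (source, destination) compartments
FLOW_ROUTES = {
    "innovation": ("i", "e"),
    "turnover_i": ("i", "n"),
    "turnover_e": ("e", "n"),
    "learn_from_i": ("n", "i"),
    "learn_from_e": ("n", "e"),
    "exchange_i_to_e": ("i", "e"),
    "exchange_e_to_i": ("e", "i"),
}


def flow_decomposition(state: SimplexState, params: ModelParams) -> dict[str, float]:
    """Decompose the vector field into its seven directed process flows.

    Every flow is non-negative in its stated direction (see
    :data:`FLOW_ROUTES`); the signed per-compartment sums reconstruct
    :func:`rhs` exactly (same floating-point expressions).
    """
    n, i, e = state.n, state.i, state.e
    open_pair = (1.0 - params.c) * i * e
    return {
        "innovation": params.mu * i,
        "turnover_i": params.m * i,
        "turnover_e": params.m * e,
        "learn_from_i": n * i * params.si,
        "learn_from_e": n * e * params.se,
        "exchange_i_to_e": open_pair * params.se,
        "exchange_e_to_i": open_pair * params.si,
    }


def flows_to_rhs(flows: Mapping[str, float]) -> tuple[float, float, float]:
    """Signed per-compartment sums of a flow table: the reconstructed rhs."""
    deriv = {"n": 0.0, "i": 0.0, "e": 0.0}
    for name, value in flows.items():
        src, dst = FLOW_ROUTES[name]
        deriv[src] -= value
        deriv[dst] += value
    return deriv["n"], deriv["i"], deriv["e"]
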