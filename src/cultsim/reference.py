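"""Brute-force fixed-step reference integrators.

These exist purely as independent cross-checks for the adaptive solver in
:mod:`cultsim.dynamics`: the vector field is re-written inline (not imported)
and advanced with the two most transparent schemes there are — forward Euler
and the classical fixed-step fourth-order Runge-Kutta.  Batched over
parameter sets with numpy so that a million fixed steps stay affordable.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .model import ModelParams, SimplexState


def _field(y: np.ndarray, mu, m, c, se, si) -> np.ndarray:
    # inline re-statement of the compartment equations (independent of
    # cultsim.model.rhs on purpose)
    n = y[:, 0]
    i = y[:, 1]
    e = y[:, 2]
    dn = m * i + m * e - n * e * se - n * i * si
    di = -mu * i - m * i + n * i * si + (1.0 - c) * e * i * si - (1.0 - c) * i * e * se
    de = mu * i - m * e + n * e * se - (1.0 - c) * e * i * si + (1.0 - c) * i * e * se
    return np.stack([dn, di, de], axis=1)


def fixed_step_trajectory(
    params_list: Sequence[ModelParams],
    initial_list: Sequence[SimplexState],
    t_max: float,
    h: float,
    method: str = "rk4",
    n_record: int = 101,
):
    """Integrate a batch of parameter sets with a fixed step ``h``.

    Returns ``(times, paths)`` with ``times`` of shape ``(n_record,)`` evenly
    spaced on ``[0, t_max]`` and ``paths`` of shape ``(n_record, B, 3)``.
    The total step count ``t_max / h`` must be an integer multiple of
    ``n_record - 1``.
    """
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown method {method!r}")
    n_steps = int(round(t_max / h))
    if abs(n_steps * h - t_max) > 1e-9 * max(1.0, t_max):
        raise ValueError("t_max must be an integer number of steps")
    if n_steps % (n_record - 1):
        raise ValueError("n_steps must be divisible by n_record - 1")
    stride = n_steps // (n_record - 1)

    mu = np.array([p.mu for p in params_list])
    m = np.array([p.m for p in params_list])
    c = np.array([p.c for p in params_list])
    se = np.array([p.se for p in params_list])
    si = np.array([p.si for p in params_list])
    y = np.stack([s.as_array() for s in initial_list]).astype(float)

    times = np.linspace(0.0, t_max, n_record)
    paths = np.empty((n_record, y.shape[0], 3))
    paths[0] = y
    rec = 1
    for k in range(n_steps):
        if method == "euler":
            y = y + h * _field(y, mu, m, c, se, si)
        else:
            k1 = _field(y, mu, m, c, se, si)
            k2 = _field(y + 0.5 * h * k1, mu, m, c, se, si)
            k3 = _field(y + 0.5 * h * k2, mu, m, c, se, si)
            k4 = _field(y + h * k3, mu, m, c, se, si)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (k + 1) % stride == 0:
            paths[rec] = y
            rec += 1
    return times, paths
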