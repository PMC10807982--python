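"""Configuration loading and CSV serialization.

CSV conventions: UNIX newlines, '.' decimal separator, full double precision
(17 significant digits) so files round-trip bitwise through the matching
readers.  Sweep grids are written long-format with an explicit reachability
column; unreachable cells have an *empty* value field, never a sentinel
number.  The config file dialect is YAML (flat key-value mapping);
command-line flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .errors import ConfigError
from .model import ModelParams, SimplexState
from .sweeps import SweepGrid

COMMANDS = (
    "simulate", "equilibrium", "sweep-th", "sweep-eq",
    "critical-curve", "critical-ratio", "abm", "robustness",
)

#: parameters a command must have once defaults are merged
_REQUIRED = {
    "simulate": ("m", "c", "se"),
    "equilibrium": ("m", "c", "se"),
    "robustness": ("m", "c", "se", "seed"),
    "sweep-th": ("se", "m_grid", "c_grid"),
    "sweep-eq": ("c", "m_grid", "se_grid"),
    "critical-curve": ("se", "m_grid"),
    "critical-ratio": ("c", "se"),
    "abm": ("m", "c", "se", "pop_size", "seed"),
}

_DEFAULTS = {
    "mu": 0.01,
    "si": 0.1,
    "n0": 0.0,
    "i0": 1.0,
    "e0": 0.0,
    "threshold": 0.5,
    "t_max": 500.0,
    "resolution": 1001,
    "mode": "analytic",
    "n_starts": 20,
    "replicates": 1,
}


@dataclass
class RunConfig:
    """Validated settings for one CLI run."""

    command: str
    mu: float = 0.01
    m: float | None = None
    c: float | None = None
    se: float | None = None
    si: float = 0.1
    n0: float = 0.0
    i0: float = 1.0
    e0: float = 0.0
    threshold: float = 0.5
    t_max: float = 500.0
    resolution: int = 1001
    m_grid: str | None = None
    c_grid: str | None = None
    se_grid: str | None = None
    mode: str = "analytic"
    pop_size: int | None = None
    replicates: int = 1
    n_starts: int = 20
    seed: int | None = None
    out: str | None = None
    plot: bool = False

    def params(self, **overrides) -> ModelParams:
        values = {"mu": self.mu, "m": self.m, "c": self.c,
                  "se": self.se, "si": self.si}
        values.update(overrides)
        missing = [k for k, v in values.items() if v is None]
        if missing:
            raise ConfigError(f"missing model parameter(s): {missing}")
        return ModelParams(**{k: float(v) for k, v in values.items()})

    def initial(self) -> SimplexState:
        return SimplexState.from_fractions(self.n0, self.i0, self.e0)


_VALID_KEYS = tuple(f.name for f in fields(RunConfig) if f.name != "command")


def parse_grid(spec) -> np.ndarray:
    """Parse a grid definition: 'start:stop:num' or an explicit list."""
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ConfigError(
                f"grid {spec!r} must have the form 'start:stop:num'"
            )
        try:
            start, stop, num = float(parts[0]), float(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ConfigError(f"malformed grid {spec!r}: {exc}") from exc
    elif isinstance(spec, (list, tuple, np.ndarray)):
        values = np.asarray(spec, dtype=float)
        if values.size == 0 or np.any(np.diff(values) <= 0):
            raise ConfigError("explicit grid must be non-empty and increasing")
        return values
    else:
        raise ConfigError(f"cannot interpret grid definition {spec!r}")
    if num < 1:
        raise ConfigError("grid must have at least one point")
    return np.linspace(start, stop, num)


def load_config(
    command: str,
    config_path: str | Path | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Merge defaults, an optional YAML file, and flag overrides.

    Precedence (lowest to highest): built-in defaults, file values, flags.
    Unknown keys are rejected with the list of valid ones.
    """
    if command not in COMMANDS:
        raise ConfigError(f"unknown command {command!r}; valid: {list(COMMANDS)}")
    merged: dict = dict(_DEFAULTS)
    if config_path is not None:
        raw = yaml.safe_load(Path(config_path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        if "command" in raw and raw["command"] != command:
            raise ConfigError(
                f"config file requests command {raw['command']!r} but "
                f"{command!r} was invoked"
            )
        raw.pop("command", None)
        merged.update(raw)
    for key, value in (overrides or {}).items():
        if value is not None:
            merged[key] = value
    unknown = sorted(set(merged) - set(_VALID_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) {unknown}; valid keys: "
            f"{sorted(_VALID_KEYS)}"
        )
    cfg = RunConfig(command=command, **merged)
    missing = [k for k in _REQUIRED[command] if getattr(cfg, k) is None]
    if missing:
        raise ConfigError(
            f"command {command!r} requires {missing} (no default exists)"
        )
    return cfg


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write ``t,n,i,e`` rows at full double precision."""
    with open(path, "w", newline="\n") as fh:
        fh.write("t,n,i,e\n")
        for t, (n, i, e) in zip(traj.times, traj.states):
            fh.write(f"{_fmt(t)},{_fmt(n)},{_fmt(i)},{_fmt(e)}\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV; re-validates the simplex invariant on load."""
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["t", "n", "i", "e"]
    if list(frame.columns) != expected:
        raise ConfigError(
            f"trajectory file must have columns {expected}, got "
            f"{list(frame.columns)}"
        )
    return Trajectory(
        times=frame["t"].to_numpy(),
        states=frame[["n", "i", "e"]].to_numpy(),
        params=None,
    )


def write_sweep(grid: SweepGrid, path: str | Path) -> None:
    """Long-format CSV ``axis1,axis2,value,reachable``; unreachable cells
    have an empty value field and ``reachable=false``."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            f"{grid.axis1_name},{grid.axis2_name},{grid.value_name},reachable\n"
        )
        for j, a1 in enumerate(grid.axis1_values):
            for k, a2 in enumerate(grid.axis2_values):
                if grid.reachable[j, k]:
                    value = _fmt(grid.values[j, k])
                    flag = "true"
                else:
                    value = ""
                    flag = "false"
                fh.write(f"{_fmt(a1)},{_fmt(a2)},{value},{flag}\n")


def read_sweep(path: str | Path) -> SweepGrid:
    """Read a long-format sweep CSV back into a :class:`SweepGrid`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] != 4 or list(frame.columns)[-1] != "reachable":
        raise ConfigError(
            "sweep file must have columns axis1,axis2,value,reachable"
        )
    a1_name, a2_name, value_name = frame.columns[:3]
    a1 = np.unique(frame[a1_name].to_numpy())
    a2 = np.unique(frame[a2_name].to_numpy())
    values = np.full((a1.size, a2.size), np.nan)
    reachable = np.zeros_like(values, dtype=bool)
    j = np.searchsorted(a1, frame[a1_name].to_numpy())
    k = np.searchsorted(a2, frame[a2_name].to_numpy())
    flags = frame["reachable"].astype(str).str.lower() == "true"
    raw = frame[value_name].to_numpy(dtype=float)
    values[j, k] = raw
    reachable[j, k] = flags.to_numpy()
    if np.any(reachable & ~np.isfinite(values)):
        raise ConfigError("reachable cell with missing value in sweep file")
    return SweepGrid(
        axis1_name=a1_name, axis1_values=a1,
        axis2_name=a2_name, axis2_values=a2,
        value_name=value_name, values=values, reachable=reachable,
    )
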