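"""Exception hierarchy for cultsim."""

from __future__ import annotations


class CultsimError(Exception):
    """Base class for all cultsim errors."""


class ParameterError(CultsimError, ValueError):
    """A model parameter is missing, unknown, or out of its admissible range."""


class SimplexError(CultsimError, ValueError):
    """A compartment state violates the simplex constraints."""


class ConfigError(CultsimError, ValueError):
    """A run configuration is malformed (unknown key, missing field, bad grid)."""


class IntegrationError(CultsimError, RuntimeError):
    """The ODE solver failed; carries the last good state reached."""

    def __init__(self, message: str, *, t: float | None = None, last_state=None):
        super().__init__(message)
        self.t = t
        self.last_state = last_state


class HorizonError(CultsimError, RuntimeError):
    """The threshold is reachable at equilibrium but the integration horizon
    was too small to observe the crossing.  Distinct from genuine
    unreachability, which is reported via ``ThresholdResult.reached``."""


class NonConvergenceError(CultsimError, RuntimeError):
    """Long-horizon integration reached its cap without settling to an
    equilibrium; carries the residual achieved."""

    def __init__(self, message: str, *, residual: float | None = None, state=None):
        super().__init__(message)
        self.residual = residual
        self.state = state


class StencilError(CultsimError, RuntimeError):
    """A finite-difference stencil point has an unreachable threshold."""


class RobustnessError(CultsimError, RuntimeError):
    """Numerical equilibria from different starting conditions disagree
    beyond tolerance (or disagree with the closed form)."""
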