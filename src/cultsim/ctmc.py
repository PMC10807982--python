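"""Finite-population stochastic counterpart of the compartment ODEs.

A continuous-time Markov chain on integer occupancies ``(N_n, N_i, N_e)``
with seven event channels (innovation, two turnover channels, two
naive-learning channels, two conservatism-gated exchange channels).  The
channel rates are scaled so that the expected drift of the *fractions*
equals the deterministic vector field exactly — a pairwise channel between
classes with fractions ``x`` and ``y`` fires at total rate ``N * x * y * s``
and moves one individual — which makes the chain an independent oracle for
the mean-field ODE and a demonstrator of finite-size effects (at small N
the efficient trait can be lost by drift even where the ODE persists).

Simulation is exact and event-driven (Gillespie's direct method); there is
no discrete round structure and no imposed ordering of processes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .model import ModelParams

#: event channels and their stoichiometry on (N_n, N_i, N_e)
CHANNEL_STOICHIOMETRY = {
    "innovation": (0, -1, 1),
    "turnover_i": (1, -1, 0),
    "turnover_e": (1, 0, -1),
    "learn_from_e": (-1, 0, 1),
    "learn_from_i": (-1, 1, 0),
    "exchange_i_to_e": (0, -1, 1),
    "exchange_e_to_i": (0, 1, -1),
}


@dataclass(frozen=True)
class AgentPopulation:
    """Integer occupancies of the three compartments.

    ``counts`` is ``(naive, inefficient, efficient)`` and must sum to ``N``.
    """

    N: int
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ParameterError(f"population size must be >= 1, got {self.N}")
        if len(self.counts) != 3 or any(
            (not isinstance(k, (int, np.integer)) or k < 0) for k in self.counts
        ):
            raise ParameterError(
                f"counts must be three non-negative integers, got {self.counts!r}"
            )
        if sum(self.counts) != self.N:
            raise ParameterError(
                f"counts {self.counts} must sum to N = {self.N}"
            )

    @classmethod
    def all_inefficient(cls, N: int) -> "AgentPopulation":
        return cls(N, (0, N, 0))

    def fractions(self) -> np.ndarray:
        return np.array(self.counts, dtype=float) / self.N


def event_rates(pop: AgentPopulation, params: ModelParams) -> dict[str, float]:
    """Per-channel total event rates for the current occupancy.

    Dividing each stoichiometry-weighted rate by N recovers the
    deterministic vector field at the occupancy fractions exactly.
    """
    nn, ni, ne = pop.counts
    n_tot = pop.N
    open_pairs = (1.0 - params.c) * ni * ne / n_tot
    return {
        "innovation": ni * params.mu,
        "turnover_i": ni * params.m,
        "turnover_e": ne * params.m,
        "learn_from_e": nn * ne * params.se / n_tot,
        "learn_from_i": nn * ni * params.si / n_tot,
        "exchange_i_to_e": open_pairs * params.se,
        "exchange_e_to_i": open_pairs * params.si,
    }


@dataclass(frozen=True)
class CountTrajectory:
    """Event-time sample path of compartment counts.

    ``times[0] = 0`` holds the initial occupancy; each subsequent row is the
    occupancy just after an event.  The path is right-continuous: the state
    on ``[times[k], times[k+1])`` is ``counts[k]``.
    """

    times: np.ndarray
    counts: np.ndarray
    N: int
    params: ModelParams
    seed: int

    def fractions_at(self, query_times) -> np.ndarray:
        """Compartment fractions at each query time (step interpolation)."""
        q = np.asarray(query_times, dtype=float)
        idx = np.searchsorted(self.times, q, side="right") - 1
        if np.any(idx < 0):
            raise ParameterError("query times must be >= 0")
        return self.counts[idx] / self.N

    @property
    def final(self) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.counts[-1])


def simulate_ctmc(
    pop0: AgentPopulation,
    params: ModelParams,
    t_max: float,
    seed: int,
) -> CountTrajectory:
    """Exact event-driven sample path on ``[0, t_max]``.

    Deterministic given ``seed``.  The path ends either at the last event
    before ``t_max`` or as soon as the total rate hits zero (the all-naive
    occupancy is absorbing).
    """
    if not t_max > 0:
        raise ParameterError(f"t_max must be positive, got {t_max!r}")
    rng = random.Random(int(seed))
    nn, ni, ne = (int(k) for k in pop0.counts)
    n_tot = pop0.N
    mu, m, c, se, si = params.mu, params.m, params.c, params.se, params.si
    one_minus_c = 1.0 - c

    t = 0.0
    times = [0.0]
    history = [(nn, ni, ne)]
    while True:
        r_innov = ni * mu
        r_turn_i = ni * m
        r_turn_e = ne * m
        r_learn_e = nn * ne * se / n_tot
        r_learn_i = nn * ni * si / n_tot
        open_pairs = one_minus_c * ni * ne / n_tot
        r_ex_ie = open_pairs * se
        r_ex_ei = open_pairs * si
        total = (r_innov + r_turn_i + r_turn_e + r_learn_e + r_learn_i
                 + r_ex_ie + r_ex_ei)
        if total <= 0.0:
            break
        t += rng.expovariate(total)
        if t > t_max:
            break
        u = rng.random() * total
        if u < r_innov:
            ni -= 1; ne += 1
        elif u < r_innov + r_turn_i:
            ni -= 1; nn += 1
        elif u < r_innov + r_turn_i + r_turn_e:
            ne -= 1; nn += 1
        elif u < r_innov + r_turn_i + r_turn_e + r_learn_e:
            nn -= 1; ne += 1
        elif u < r_innov + r_turn_i + r_turn_e + r_learn_e + r_learn_i:
            nn -= 1; ni += 1
        elif u < total - r_ex_ei:
            ni -= 1; ne += 1
        else:
            ne -= 1; ni += 1
        times.append(t)
        history.append((nn, ni, ne))
    return CountTrajectory(
        times=np.array(times),
        counts=np.array(history, dtype=np.int64),
        N=n_tot,
        params=params,
        seed=int(seed),
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate-averaged fractions at fixed sample times."""

    times: np.ndarray
    mean: np.ndarray       # (T, 3)
    sem: np.ndarray        # (T, 3) Monte-Carlo standard error of the mean
    n_replicates: int
    extinct_fraction: float  # replicates ending all-naive


def ensemble_mean(
    pop0: AgentPopulation,
    params: ModelParams,
    t_max: float,
    sample_times,
    n_replicates: int,
    seed: int,
) -> EnsembleSummary:
    """Replicate ensemble of CTMC paths, sampled on a fixed time grid.

    Per-replicate seeds are derived from ``seed`` via a
    ``numpy.random.SeedSequence`` so the ensemble is reproducible and the
    replicates independent.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    sample_times = np.asarray(sample_times, dtype=float)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    paths = np.empty((n_replicates, sample_times.size, 3))
    n_extinct = 0
    for r, s in enumerate(child_seeds):
        traj = simulate_ctmc(pop0, params, t_max, int(s))
        paths[r] = traj.fractions_at(sample_times)
        if traj.final == (pop0.N, 0, 0):
            n_extinct += 1
    mean = paths.mean(axis=0)
    if n_replicates > 1:
        sem = paths.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    else:
        sem = np.zeros_like(mean)
    return EnsembleSummary(
        times=sample_times, mean=mean, sem=sem,
        n_replicates=n_replicates,
        extinct_fraction=n_extinct / n_replicates,
    )
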