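"""Agent-based frequency-dependent Moran simulation with finite mutation.

Each period: (1) a group of ``N`` players is drawn without replacement from
the well-mixed population of ``M``; (2) the group plays the public goods
game and its members receive the resulting payoffs (everyone else earns 0
this period, hence baseline fitness ``exp(0) = 1``); (3) fitness is
``exp(omega * payoff)``; (4) a "genetic pool" reproduction step replaces
one uniformly chosen individual with an offspring whose type is drawn with
probability proportional to the summed fitness of each type; (5) the
newborn mutates to one of the other two strategies with probability ``mu``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analytic import STRATEGIES
from .game import GroupComposition, group_payoffs
from .params import GameParameters

__all__ = [
    "PopulationState",
    "SimulationConfig",
    "SimulationTrace",
    "PeriodResult",
    "mutate",
    "play_one_period",
    "genetic_pool_update",
    "run_simulation",
    "parameter_sweep",
    "SWEEPABLE_PARAMETERS",
]

#: Parameters :func:`parameter_sweep` can vary (plus ``initial_state``).
SWEEPABLE_PARAMETERS = ("alpha", "r", "c", "delta", "gamma", "omega", "mu")


@dataclass(frozen=True)
class PopulationState:
    """Strategy counts at population scale: X cooperators, Y defectors, Z punishers."""

    X: int
    Y: int
    Z: int

    def __post_init__(self) -> None:
        if min(self.X, self.Y, self.Z) < 0:
            raise ValueError("population counts must be non-negative")

    @property
    def M(self) -> int:
        return self.X + self.Y + self.Z

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.X, self.Y, self.Z)


@dataclass(frozen=True)
class SimulationConfig:
    """Run-control knobs of one simulation.

    ``burn_in`` periods are excluded from the long-run average frequencies;
    ``None`` defaults to 10% of ``periods`` (figure-reproduction recipes
    pass 0 so averages cover the full run). ``record_every`` thins the
    stored trace without affecting the dynamics.
    """

    periods: int
    seed: int
    initial_state: PopulationState
    burn_in: int | None = None
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.periods < 1:
            raise ValueError("periods must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.burn_in is not None and not 0 <= self.burn_in < self.periods:
            raise ValueError("require 0 <= burn_in < periods")

    @property
    def effective_burn_in(self) -> int:
        return self.periods // 10 if self.burn_in is None else self.burn_in


@dataclass(frozen=True)
class PeriodResult:
    """Outcome of one period's game: sampled counts and per-type payoffs.

    ``payoffs`` entries are defined for all three types; the entry of a
    type with zero sampled members is counterfactual and carries no
    fitness weight in the update.
    """

    sampled: tuple[int, int, int]
    payoffs: tuple[float, float, float]


@dataclass
class SimulationTrace:
    """Recorded trajectory plus long-run average strategy frequencies."""

    times: np.ndarray
    counts: np.ndarray
    mean_frequencies: np.ndarray
    params: GameParameters = field(repr=False, default=None)
    config: SimulationConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period": self.times,
                "X": self.counts[:, 0],
                "Y": self.counts[:, 1],
                "Z": self.counts[:, 2],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mutate(strategy: str, mu: float, rng: np.random.Generator) -> str:
    """Switch to one of the two other strategies with probability ``mu``."""
    if not 0 <= mu < 1:
        raise ValueError(f"mutation rate must be in [0, 1), got {mu}")
    if mu > 0.0 and rng.random() < mu:
        others = [s for s in STRATEGIES if s != strategy]
        return others[rng.integers(2)]
    return strategy


def play_one_period(
    state: PopulationState,
    params: GameParameters,
    rng: np.random.Generator,
    _cache: dict | None = None,
) -> PeriodResult:
    """Sample one game group and compute this period's payoffs.

    The group composition is multivariate hypergeometric over the current
    population counts. Only sampled individuals earn a payoff this period.
    """
    if state.M != params.M:
        raise ValueError(f"state sums to {state.M}, expected M={params.M}")
    sx, sy, sz = (int(v) for v in rng.multivariate_hypergeometric(state.as_tuple(), params.N))
    key = (sx, sy, sz)
    if _cache is not None and key in _cache:
        payoffs = _cache[key]
    else:
        gp = group_payoffs(params, GroupComposition(sx, sy, sz))
        payoffs = (gp.P_x, gp.P_y, gp.P_z)
        if _cache is not None:
            _cache[key] = payoffs
    return PeriodResult(sampled=key, payoffs=payoffs)


def genetic_pool_update(
    state: PopulationState,
    result: PeriodResult,
    params: GameParameters,
    rng: np.random.Generator,
    literal_pool: bool = False,
) -> PopulationState:
    """One Moran birth-death event with genetic-pool reproduction.

    A uniformly chosen individual dies; the replacing offspring's type is
    drawn with probability proportional to each type's total fitness mass
    (sampled members contribute ``exp(omega * payoff)``, everyone else 1),
    then passes through :func:`mutate`. With ``literal_pool=True`` the pool
    of M offspring is materialized and one drawn uniformly — distributionally
    identical, kept for cross-validation.
    """
    counts = list(state.as_tuple())
    M = state.M
    w = params.omega
    mass = [
        ns * math.exp(w * p) + (n - ns)
        for n, ns, p in zip(counts, result.sampled, result.payoffs)
    ]
    total = mass[0] + mass[1] + mass[2]
    if not total > 0.0 or not math.isfinite(total):
        raise RuntimeError("non-positive or non-finite total fitness mass")

    if literal_pool:
        pool = rng.multinomial(M, [m / total for m in mass])
        pick = rng.integers(M)
        born = 0 if pick < pool[0] else (1 if pick < pool[0] + pool[1] else 2)
    else:
        u = rng.random() * total
        born = 0 if u < mass[0] else (1 if u < mass[0] + mass[1] else 2)

    born_label = mutate(STRATEGIES[born], params.mu, rng)
    born = STRATEGIES.index(born_label)

    d = rng.integers(M)
    die = 0 if d < counts[0] else (1 if d < counts[0] + counts[1] else 2)

    counts[die] -= 1
    counts[born] += 1
    return PopulationState(*counts)


def run_simulation(config: SimulationConfig, params: GameParameters) -> SimulationTrace:
    """Iterate the per-period pipeline and record the trajectory.

    Deterministic given ``config.seed``. Records the population state every
    ``record_every`` periods; ``mean_frequencies`` averages the recorded
    states after the burn-in window.
    """
    if config.initial_state.M != params.M:
        raise ValueError("initial state population must sum to M")
    rng = np.random.default_rng(config.seed)
    state = config.initial_state
    cache: dict = {}
    times = []
    counts = []
    for t in range(1, config.periods + 1):
        result = play_one_period(state, params, rng, _cache=cache)
        state = genetic_pool_update(state, result, params, rng)
        if t % config.record_every == 0:
            times.append(t)
            counts.append(state.as_tuple())
    times_arr = np.asarray(times, dtype=np.int64)
    counts_arr = np.asarray(counts, dtype=np.int64)
    post = counts_arr[times_arr > config.effective_burn_in]
    if len(post) == 0:
        raise ValueError("no recorded periods after burn-in; lower burn_in")
    mean_freq = post.mean(axis=0) / params.M
    return SimulationTrace(
        times=times_arr,
        counts=counts_arr,
        mean_frequencies=mean_freq,
        params=params,
        config=config,
    )


def _replicate_seed(base_seed: int, grid_index: int, replicate: int) -> int:
    """Derive an independent stream seed per (grid point, replicate)."""
    ss = np.random.SeedSequence([int(base_seed), int(grid_index), int(replicate)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _format_value(value):
    if isinstance(value, PopulationState):
        return f"{value.X}-{value.Y}-{value.Z}"
    if isinstance(value, (tuple, list)):
        return "-".join(str(v) for v in value)
    return float(value)


def parameter_sweep(
    base_params: GameParameters,
    param_name: str,
    grid: Sequence | Iterable,
    config: SimulationConfig,
    replicates: int,
) -> pd.DataFrame:
    """Replicated simulations along a grid of one parameter.

    ``param_name`` is one of ``alpha, r, c, delta, gamma, omega, mu`` or
    ``initial_state`` (grid entries then being (X, Y, Z) count triples).
    Each grid point runs ``replicates`` independent simulations whose seeds
    are derived from ``config.seed`` through a spawned seed sequence keyed
    by (grid index, replicate index). Reports the mean and standard
    deviation of each strategy's long-run mean frequency.
    """
    if param_name not in SWEEPABLE_PARAMETERS + ("initial_state",):
        raise ValueError(
            f"cannot sweep {param_name!r}; choose one of "
            f"{SWEEPABLE_PARAMETERS + ('initial_state',)}"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for gi, value in enumerate(grid):
        if param_name == "initial_state":
            init = value if isinstance(value, PopulationState) else PopulationState(*value)
            params = base_params
        else:
            init = config.initial_state
            params = base_params.replace(**{param_name: float(value)})
        freqs = np.empty((replicates, 3))
        for ri in range(replicates):
            cfg = dataclasses.replace(
                config, seed=_replicate_seed(config.seed, gi, ri), initial_state=init
            )
            freqs[ri] = run_simulation(cfg, params).mean_frequencies
        mean = freqs.mean(axis=0)
        sd = freqs.std(axis=0, ddof=1) if replicates > 1 else np.zeros(3)
        rows.append(
            {
                "param_name": param_name,
                "param_value": _format_value(value),
                "mean_freq_C": mean[0],
                "mean_freq_D": mean[1],
                "mean_freq_P": mean[2],
                "sd_freq_C": sd[0],
                "sd_freq_D": sd[1],
                "sd_freq_P": sd[2],
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
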