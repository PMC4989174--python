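"""Small-mutation-limit stochastic dynamics of the three-strategy game.

When the mutation rate is vanishingly small the population is monomorphic
almost all of the time: a lone mutant either dies out or fixes before the
next mutation arrives. Long-run behaviour therefore reduces to a Markov
chain over the three homogeneous states (all-cooperator, all-defector,
all-punisher) whose transition rates are single-mutant fixation
probabilities of the frequency-dependent Moran process.

The pipeline implemented here:

1. hypergeometric group sampling in a two-type population,
2. focal-player expected payoffs (the focal individual holds one group
   slot; its N-1 co-players are drawn without replacement from the other
   M-1 individuals),
3. exponential fitness ``F = exp(omega * P)``,
4. Moran birth-death transition rates and the classic ratio-product
   fixation probability ``rho = 1 / (1 + sum_k prod_{l<=k} theta_l)`` with
   ``theta_l = T_l^- / T_l^+``, accumulated in log space,
5. the embedded 3-state chain (each of the two possible mutant types
   appears with probability 1/2) and its stationary distribution, computed
   redundantly by eigen-decomposition and by direct linear solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .game import GroupComposition, group_payoffs
from .params import GameParameters

__all__ = [
    "STRATEGIES",
    "StrategyPair",
    "PairwisePopulation",
    "TransitionRates",
    "FixationMatrix",
    "StationaryDistribution",
    "group_sampling_pmf",
    "expected_payoff_pair",
    "fitness",
    "moran_transition_probs",
    "fixation_probability",
    "log_fixation_probability",
    "fixation_matrix",
    "embedded_transition_matrix",
    "stationary_distribution",
    "alpha_scan",
]

#: Strategy labels, in the fixed state order of the embedded chain.
STRATEGIES = ("C", "D", "P")


def _check_strategy(label: str) -> str:
    if label not in STRATEGIES:
        raise ValueError(f"unknown strategy {label!r}; expected one of {STRATEGIES}")
    return label


@dataclass(frozen=True)
class StrategyPair:
    """An ordered resident/mutant pair of distinct strategies."""

    resident: str
    mutant: str

    def __post_init__(self) -> None:
        _check_strategy(self.resident)
        _check_strategy(self.mutant)
        if self.resident == self.mutant:
            raise ValueError("resident and mutant strategies must differ")


@dataclass(frozen=True)
class PairwisePopulation:
    """A two-type population state: ``m_i`` mutants, ``M - m_i`` residents."""

    pair: StrategyPair
    m_i: int


@dataclass(frozen=True)
class TransitionRates:
    """One-step probabilities of the mutant count moving up or down."""

    T_plus: float
    T_minus: float


@dataclass(frozen=True)
class FixationMatrix:
    """Fixation probabilities ``rho[(mutant, resident)]`` for all six pairs."""

    rho: Mapping[tuple[str, str], float]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.rho[key]


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run probabilities of the three homogeneous states."""

    pi_C: float
    pi_D: float
    pi_P: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pi_C, self.pi_D, self.pi_P])


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def group_sampling_pmf(M: int, m_i: int, N: int, k: int) -> float:
    """Probability of drawing ``k`` type-i players into a group of ``N``.

    Sampling is without replacement from a population of ``M`` with ``m_i``
    individuals of type i: the hypergeometric mass
    ``C(m_i, k) C(M - m_i, N - k) / C(M, N)``, evaluated through log-gamma
    so population sizes of 10^4 and beyond stay in range.
    """
    if not (0 <= m_i <= M and 0 <= k <= N <= M):
        raise ValueError(
            f"require 0 <= m_i <= M and 0 <= k <= N <= M, "
            f"got M={M}, m_i={m_i}, N={N}, k={k}"
        )
    if k > m_i or N - k > M - m_i:
        return 0.0
    return float(
        math.exp(_log_comb(m_i, k) + _log_comb(M - m_i, N - k) - _log_comb(M, N))
    )


def _hypergeom_weights(M: int, good: np.ndarray, draws: int) -> np.ndarray:
    """Row-stochastic matrix W[g, k] = P(k successes | good[g]) via log-gamma."""
    k = np.arange(draws + 1)
    g = np.asarray(good, dtype=float)[:, None]
    kk = k[None, :].astype(float)
    feasible = (kk <= g) & (draws - kk <= M - g)
    logw = np.where(
        feasible,
        _log_comb(g, kk) + _log_comb(M - g, draws - kk) - _log_comb(float(M), float(draws)),
        -np.inf,
    )
    return np.exp(logw)


def _focal_payoff(params: GameParameters, focal: str, other: str, k_same: int) -> float:
    """Payoff of a focal player with ``k_same`` co-players of its own type.

    The remaining ``N - 1 - k_same`` co-players are of the ``other`` type.
    """
    counts = {"C": 0, "D": 0, "P": 0}
    counts[focal] = k_same + 1
    counts[other] = params.N - 1 - k_same
    comp = GroupComposition(counts["C"], counts["D"], counts["P"])
    payoffs = group_payoffs(params, comp)
    return {"C": payoffs.P_x, "D": payoffs.P_y, "P": payoffs.P_z}[focal]


def _pair_expected_payoffs(
    params: GameParameters, type_i: str, type_j: str
) -> tuple[np.ndarray, np.ndarray]:
    """Expected payoffs of both types at every mixed count m_i = 1..M-1.

    Returns arrays ``(P_i, P_j)`` indexed by ``m_i - 1``. The focal player
    occupies one slot; its N-1 co-players are hypergeometric over the
    remaining M-1 individuals.
    """
    M, N = params.M, params.N
    m = np.arange(1, M)
    pay_i = np.array([_focal_payoff(params, type_i, type_j, k) for k in range(N)])
    pay_j = np.array([_focal_payoff(params, type_j, type_i, k) for k in range(N)])
    W_i = _hypergeom_weights(M - 1, m - 1, N - 1)
    W_j = _hypergeom_weights(M - 1, (M - m) - 1, N - 1)
    return W_i @ pay_i, W_j @ pay_j


def expected_payoff_pair(
    params: GameParameters, state: PairwisePopulation, focal: str
) -> float:
    """Expected one-period payoff of a focal player in a two-type population.

    The focal player is guaranteed a group slot; the number of co-players
    sharing its strategy is hypergeometric over the other ``M - 1``
    individuals. Covers all six ordered type pairings.
    """
    _check_strategy(focal)
    pair = state.pair
    if focal == pair.mutant:
        m_focal, other = state.m_i, pair.resident
    elif focal == pair.resident:
        m_focal, other = params.M - state.m_i, pair.mutant
    else:
        raise ValueError(f"focal {focal!r} is not part of pair {pair}")
    if m_focal < 1:
        raise ValueError(f"focal type {focal!r} has no individuals in this state")
    total = 0.0
    for k in range(params.N):
        w = group_sampling_pmf(params.M - 1, m_focal - 1, params.N - 1, k)
        if w:
            total += w * _focal_payoff(params, focal, other, k)
    return total


def fitness(params: GameParameters, payoff: float) -> float:
    """Exponential fitness ``exp(omega * payoff)``, positive for any payoff."""
    return math.exp(params.omega * payoff)


def moran_transition_probs(
    params: GameParameters, state: PairwisePopulation
) -> TransitionRates:
    """Frequency-dependent Moran one-step rates for the mutant count.

    ``T_plus = [m_i F_i / (m_i F_i + m_j F_j)] * (m_j / M)`` and symmetrically
    for ``T_minus``; both are zero in the absorbing states ``m_i in {0, M}``.
    The ratio ``T_minus / T_plus`` collapses to ``F_j / F_i``, the quantity
    the fixation formula is built from.
    """
    M = params.M
    m_i = state.m_i
    if not 0 <= m_i <= M:
        raise ValueError(f"mutant count {m_i} outside [0, {M}]")
    if m_i in (0, M):
        return TransitionRates(0.0, 0.0)
    m_j = M - m_i
    a = params.omega * expected_payoff_pair(params, state, state.pair.mutant)
    b = params.omega * expected_payoff_pair(params, state, state.pair.resident)
    shift = max(a, b)  # overflow-safe fitness ratio
    wi = m_i * math.exp(a - shift)
    wj = m_j * math.exp(b - shift)
    return TransitionRates(
        T_plus=(wi / (wi + wj)) * (m_j / M),
        T_minus=(wj / (wi + wj)) * (m_i / M),
    )


def log_fixation_probability(params: GameParameters, pair: StrategyPair) -> float:
    """Natural log of the single-mutant fixation probability; always finite.

    Uses the birth-death ratio-product identity
    ``rho = 1 / (1 + sum_{k=1}^{M-1} prod_{l=1}^{k} theta_l)`` with
    ``theta_l = T_l^- / T_l^+ = exp(-omega (P_i(l) - P_j(l)))``. The
    products are accumulated as sums of ``log theta`` and the outer sum via
    log-sum-exp, so strong selection and large populations stay in range.
    """
    P_i, P_j = _pair_expected_payoffs(params, pair.mutant, pair.resident)
    log_theta = params.omega * (P_j - P_i)
    log_terms = np.concatenate(([0.0], np.cumsum(log_theta)))
    return -float(logsumexp(log_terms))


def fixation_probability(params: GameParameters, pair: StrategyPair) -> float:
    """Probability that a single mutant sweeps a resident population.

    Computed through :func:`log_fixation_probability`. A probability whose
    magnitude lies below the double-precision range is reported as the
    smallest positive float rather than 0, so the embedded chain never
    acquires an exactly-absorbing spurious zero; use the log variant when
    such extreme magnitudes matter.
    """
    rho = math.exp(log_fixation_probability(params, pair))
    return max(rho, 5e-324)


def fixation_matrix(params: GameParameters) -> FixationMatrix:
    """Fixation probabilities for all six ordered (mutant, resident) pairs."""
    rho = {}
    for resident in STRATEGIES:
        for mutant in STRATEGIES:
            if mutant != resident:
                rho[(mutant, resident)] = fixation_probability(
                    params, StrategyPair(resident=resident, mutant=mutant)
                )
    return FixationMatrix(rho)


def embedded_transition_matrix(params: GameParameters) -> np.ndarray:
    """Row-stochastic 3x3 matrix of the embedded chain, states (C, D, P).

    In the rare-mutation limit each of a resident's two possible mutant
    types arises with probability 1/2, so the off-diagonal entry from
    resident j to state i is ``rho_ij / 2``; diagonals absorb the rest.
    """
    rho = fixation_matrix(params)
    A = np.zeros((3, 3))
    for jj, resident in enumerate(STRATEGIES):
        for ii, mutant in enumerate(STRATEGIES):
            if ii != jj:
                A[jj, ii] = rho[(mutant, resident)] / 2.0
        A[jj, jj] = 1.0 - A[jj].sum()
    return A


def _stationary_eigen(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    order = np.argsort(np.abs(vals - 1.0))
    lead = order[0]
    if abs(vals[lead] - 1.0) > 1e-8:
        raise ValueError("matrix has no eigenvalue at 1; not row-stochastic?")
    if len(order) > 1 and abs(vals[order[1]] - 1.0) < 1e-8:
        raise ValueError("stationary distribution is not unique (reducible chain)")
    v = np.real(vecs[:, lead])
    s = v.sum()
    if s < 0:
        v = -v
        s = -s
    v = v / s
    if np.any(v < -1e-9):
        raise ValueError("leading eigenvector has a negative component")
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


def _stationary_solve(A: np.ndarray) -> np.ndarray:
    # Homogeneous system (A^T - I) pi = 0 with the normalization identity
    # sum(pi) = 1 substituted for the (redundant) last equation.
    B = A.T - np.eye(3)
    B[2, :] = 1.0
    rhs = np.array([0.0, 0.0, 1.0])
    return np.linalg.solve(B, rhs)


def stationary_distribution(matrix: np.ndarray) -> StationaryDistribution:
    """Stationary law of a row-stochastic 3x3 chain, cross-validated.

    Computed both from the unit eigenvector of the transposed matrix and
    from a direct linear solve of the balance equations with the
    normalization constraint; the two routes must agree to 1e-10 or the
    matrix is rejected as degenerate.
    """
    A = np.asarray(matrix, dtype=float)
    if A.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {A.shape}")
    if np.any(A < -1e-12) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("matrix is not row-stochastic")
    pi_eig = _stationary_eigen(A)
    pi_lin = _stationary_solve(A)
    if np.max(np.abs(pi_eig - pi_lin)) > 1e-10:
        raise ValueError(
            "eigenvector and linear-solve stationary distributions disagree; "
            "chain is near-degenerate"
        )
    pi = pi_eig / pi_eig.sum()
    return StationaryDistribution(pi_C=float(pi[0]), pi_D=float(pi[1]), pi_P=float(pi[2]))


def alpha_scan(
    params: GameParameters,
    alpha_grid: Sequence[float] | Iterable[float],
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Stationary distribution of the embedded chain along a grid of alpha.

    Returns a table with columns ``alpha, pi_C, pi_D, pi_P`` (one row per
    grid value); optionally written to ``out`` as CSV at full precision.
    """
    rows = []
    for a in alpha_grid:
        if not a > 0:
            raise ValueError(f"alpha grid values must be > 0, got {a}")
        pi = stationary_distribution(
            embedded_transition_matrix(params.replace(alpha=float(a)))
        )
        rows.append({"alpha": float(a), "pi_C": pi.pi_C, "pi_D": pi.pi_D, "pi_P": pi.pi_P})
    table = pd.DataFrame(rows, columns=["alpha", "pi_C", "pi_D", "pi_P"])
    if out is not None:
        table.to_csv(out, index=False)
    return table
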