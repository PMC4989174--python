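"""Rare-mutation analysis: sampling, expected payoffs, fixation, stationarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalepgg import (
    GameParameters,
    GroupComposition,
    PairwisePopulation,
    StrategyPair,
    alpha_scan,
    embedded_transition_matrix,
    expected_payoff_pair,
    fitness,
    fixation_matrix,
    fixation_probability,
    log_fixation_probability,
    group_payoffs,
    group_sampling_pmf,
    moran_transition_probs,
    stationary_distribution,
)

ALL_PAIRS = [
    StrategyPair(resident=r, mutant=m)
    for r in ("C", "D", "P")
    for m in ("C", "D", "P")
    if r != m
]


def params(**kw) -> GameParameters:
    base = dict(M=100, N=5, c=1.0, r=3.0, alpha=1.0, delta=1.0, gamma=0.3,
                omega=0.1, mu=0.0)
    base.update(kw)
    return GameParameters(**base)


# ---------------------------------------------------------------- sampling

def test_group_sampling_pmf_examples():
    # homogeneous population: the group is certainly all one type
    assert group_sampling_pmf(100, 100, 5, 5) == pytest.approx(1.0)
    # enumeration oracle: C(4,2) * C(6,1) / C(10,3) = 36/120
    assert group_sampling_pmf(10, 4, 3, 2) == pytest.approx(36 / 120, abs=1e-14)
    assert group_sampling_pmf(10, 4, 3, 3) == pytest.approx(
        math.comb(4, 3) / math.comb(10, 3), abs=1e-14
    )
    # infeasible draws have zero probability
    assert group_sampling_pmf(10, 2, 5, 3) == 0.0
    assert group_sampling_pmf(10, 9, 5, 1) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    M=st.integers(5, 300),
    data=st.data(),
)
def test_group_sampling_pmf_normalizes(M, data):
    m_i = data.draw(st.integers(0, M))
    N = data.draw(st.integers(2, min(M, 8)))
    total = sum(group_sampling_pmf(M, m_i, N, k) for k in range(N + 1))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_group_sampling_pmf_large_population():
    # log-gamma evaluation stays finite and normalized at M = 10^4
    total = sum(group_sampling_pmf(10_000, 3_000, 6, k) for k in range(7))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_group_sampling_pmf_rejects_bad_arguments():
    with pytest.raises(ValueError):
        group_sampling_pmf(10, 11, 3, 1)
    with pytest.raises(ValueError):
        group_sampling_pmf(10, 5, 12, 1)


# ------------------------------------------------------- expected payoffs

def brute_force_expected_payoff(p: GameParameters, pair: StrategyPair,
                                m_mutant: int, focal: str) -> float:
    """Exhaustive enumeration over the focal player's co-player composition."""
    other = pair.resident if focal == pair.mutant else pair.mutant
    m_focal = m_mutant if focal == pair.mutant else p.M - m_mutant
    total = 0.0
    for k in range(p.N):
        w = (math.comb(m_focal - 1, k)
             * math.comb(p.M - m_focal, p.N - 1 - k)
             / math.comb(p.M - 1, p.N - 1)
             if k <= m_focal - 1 and p.N - 1 - k <= p.M - m_focal else 0.0)
        if w == 0.0:
            continue
        counts = {"C": 0, "D": 0, "P": 0}
        counts[focal] = k + 1
        counts[other] = p.N - 1 - k
        gp = group_payoffs(p, GroupComposition(counts["C"], counts["D"], counts["P"]))
        total += w * {"C": gp.P_x, "D": gp.P_y, "P": gp.P_z}[focal]
    return total


def test_expected_payoff_in_monomorphic_population():
    # every group is all-cooperator: payoff is exactly 15/5 - 1 = 2
    p = params()
    state = PairwisePopulation(StrategyPair(resident="D", mutant="C"), m_i=100)
    assert expected_payoff_pair(p, state, "C") == pytest.approx(2.0, abs=1e-12)


@pytest.mark.parametrize("focal_is_mutant", [True, False])
@pytest.mark.parametrize("pair", ALL_PAIRS, ids=lambda q: f"{q.mutant}into{q.resident}")
def test_expected_payoff_matches_enumeration(pair, focal_is_mutant):
    p = params(M=10, N=3, alpha=1.8, delta=1.0, gamma=0.3)
    for m in range(1, p.M):
        focal = pair.mutant if focal_is_mutant else pair.resident
        got = expected_payoff_pair(p, PairwisePopulation(pair, m), focal)
        want = brute_force_expected_payoff(p, pair, m, focal)
        assert got == pytest.approx(want, abs=1e-12)


def test_costless_punishment_makes_C_and_P_mirror_images():
    p = params(delta=0.0, gamma=0.0)
    cp = StrategyPair(resident="P", mutant="C")
    for m in (1, 25, 70, 99):
        as_c = expected_payoff_pair(p, PairwisePopulation(cp, m), "C")
        as_p = expected_payoff_pair(p, PairwisePopulation(cp, p.M - m), "P")
        # a punisher at mirrored counts faces the identical situation
        assert as_c == pytest.approx(
            expected_payoff_pair(p, PairwisePopulation(cp, p.M - m), "P"), abs=1e-12
        )
        assert as_p == pytest.approx(as_c, abs=1e-12)


def test_expected_payoff_rejects_absent_focal():
    p = params()
    state = PairwisePopulation(StrategyPair(resident="D", mutant="C"), m_i=0)
    with pytest.raises(ValueError):
        expected_payoff_pair(p, state, "C")


# ------------------------------------------------ transitions and fixation

def test_fitness_is_exponential_and_monotone():
    assert fitness(params(omega=0.1), 0.0) == pytest.approx(1.0)
    assert fitness(params(omega=0.5), 2.0) == pytest.approx(math.e)
    assert fitness(params(omega=0.5), -3.0) > 0.0


def test_transition_rates_neutral_symmetry():
    # identical payoffs: up- and down-rates coincide; M=4, m=2 gives 1/4
    p = params(M=4, N=2, delta=0.0, gamma=0.0)
    state = PairwisePopulation(StrategyPair(resident="P", mutant="C"), m_i=2)
    rates = moran_transition_probs(p, state)
    assert rates.T_plus == pytest.approx(0.25, abs=1e-12)
    assert rates.T_minus == pytest.approx(0.25, abs=1e-12)


def test_transition_rates_boundary_states_absorb():
    p = params()
    pair = StrategyPair(resident="D", mutant="C")
    for m in (0, p.M):
        rates = moran_transition_probs(p, PairwisePopulation(pair, m))
        assert rates.T_plus == 0.0 and rates.T_minus == 0.0


@pytest.mark.parametrize("pair", ALL_PAIRS, ids=lambda q: f"{q.mutant}into{q.resident}")
def test_transition_ratio_equals_fitness_ratio(pair):
    """theta = T-/T+ must reduce to exp(-omega (P_i - P_j)) at every state."""
    p = params(M=30, N=5, alpha=1.4)
    for m in (1, 7, 15, 29):
        state = PairwisePopulation(pair, m)
        rates = moran_transition_probs(p, state)
        pi = expected_payoff_pair(p, state, pair.mutant)
        pj = expected_payoff_pair(p, state, pair.resident)
        assert rates.T_minus / rates.T_plus == pytest.approx(
            math.exp(-p.omega * (pi - pj)), rel=1e-12
        )
        assert 0.0 < rates.T_plus + rates.T_minus <= 1.0


def absorbing_chain_fixation(p: GameParameters, pair: StrategyPair) -> float:
    """Oracle: solve the absorbing birth-death chain linear system for x_1."""
    M = p.M
    A = np.zeros((M - 1, M - 1))
    b = np.zeros(M - 1)
    for m in range(1, M):
        rates = moran_transition_probs(p, PairwisePopulation(pair, m))
        row = m - 1
        A[row, row] = rates.T_plus + rates.T_minus
        if m > 1:
            A[row, row - 1] = -rates.T_minus
        if m < M - 1:
            A[row, row + 1] = -rates.T_plus
        else:
            b[row] = rates.T_plus  # x_M = 1
    return float(np.linalg.solve(A, b)[0])


@pytest.mark.parametrize("alpha", [1.0, 1.8])
@pytest.mark.parametrize("pair", ALL_PAIRS, ids=lambda q: f"{q.mutant}into{q.resident}")
def test_fixation_matches_absorbing_chain_solve(pair, alpha):
    for M in (6, 12, 20):
        p = params(M=M, N=4, alpha=alpha, omega=0.2)
        assert fixation_probability(p, pair) == pytest.approx(
            absorbing_chain_fixation(p, pair), abs=1e-10
        )


def test_fixation_neutral_limit_is_one_over_M():
    p = params(omega=1e-8)
    for pair in ALL_PAIRS:
        assert fixation_probability(p, pair) == pytest.approx(1 / p.M, rel=1e-6)


def test_fixation_free_punishment_pairs_are_neutral():
    # with delta = gamma = 0 cooperators and punishers are payoff-identical
    p = params(delta=0.0, gamma=0.0)
    for pair in (StrategyPair("C", "P"), StrategyPair("P", "C")):
        assert fixation_probability(p, pair) == pytest.approx(1 / p.M, rel=1e-9)


def test_fixation_survives_strong_selection_large_population():
    p = params(M=1000, N=5, alpha=1.8, omega=5.0)
    for pair in ALL_PAIRS:
        log_rho = log_fixation_probability(p, pair)
        assert math.isfinite(log_rho) and log_rho < 0.0
        rho = fixation_probability(p, pair)
        assert 0.0 < rho < 1.0


# ------------------------------------------- embedded chain and stationarity

def test_embedded_matrix_rows_sum_to_one(fig_params):
    A = embedded_transition_matrix(fig_params.replace(alpha=1.4))
    assert np.allclose(A.sum(axis=1), 1.0, atol=1e-14)
    assert np.all(A >= 0.0)


def test_embedded_matrix_neutral_entries():
    # near-neutral selection: every off-diagonal approaches 1/(2M)
    p = params(omega=1e-8, delta=0.0, gamma=0.0, r=1.0001, alpha=1.0)
    A = embedded_transition_matrix(p)
    off = A[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1 / (2 * p.M), rtol=1e-5)
    assert np.allclose(np.diag(A), 1 - 1 / p.M, rtol=1e-5)


def test_embedded_matrix_composes_fixation_probabilities(small_params):
    rho = fixation_matrix(small_params)
    A = embedded_transition_matrix(small_params)
    order = ("C", "D", "P")
    for j, res in enumerate(order):
        for i, mut in enumerate(order):
            if i != j:
                assert A[j, i] == pytest.approx(rho[(mut, res)] / 2, abs=1e-15)


def test_stationary_uniform_for_symmetric_chain():
    A = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    pi = stationary_distribution(A)
    assert pi.as_array() == pytest.approx(np.full(3, 1 / 3), abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_stationary_is_fixed_point_of_random_chains(seed):
    rng = np.random.default_rng(seed)
    A = rng.dirichlet(np.ones(3) * 2.0, size=3)
    pi = stationary_distribution(A).as_array()
    assert np.max(np.abs(pi @ A - pi)) < 1e-12
    assert pi.sum() == pytest.approx(1.0, abs=1e-12)


def test_stationary_rejects_reducible_chain():
    with pytest.raises(ValueError):
        stationary_distribution(np.eye(3))


def test_stationary_rejects_non_stochastic_input():
    with pytest.raises(ValueError):
        stationary_distribution(np.array([[0.5, 0.5, 0.1]] * 3))


def test_stationary_residual_on_model_chains(fig_params):
    for alpha in (1.0, 1.3, 1.8):
        A = embedded_transition_matrix(fig_params.replace(alpha=alpha))
        pi = stationary_distribution(A).as_array()
        assert np.max(np.abs(pi @ A - pi)) < 1e-10


def test_free_punishment_equalizes_C_and_P_states(fig_params):
    pi = stationary_distribution(
        embedded_transition_matrix(fig_params.replace(delta=0.0, gamma=0.0))
    )
    assert pi.pi_C == pytest.approx(pi.pi_P, abs=1e-10)


# ------------------------------------------------------------- alpha scan

def test_alpha_scan_shape_and_normalization(fig_params, tmp_path):
    out = tmp_path / "scan.csv"
    grid = [round(1.0 + 0.1 * i, 1) for i in range(11)]
    table = alpha_scan(fig_params, grid, out=out)
    assert list(table.columns) == ["alpha", "pi_C", "pi_D", "pi_P"]
    assert len(table) == 11
    sums = table[["pi_C", "pi_D", "pi_P"]].sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12)
    assert out.exists()
    reread = np.loadtxt(out, delimiter=",", skiprows=1)
    assert reread.shape == (11, 4)


def test_alpha_scan_defector_time_shrinks_with_scale(fig_params):
    grid = [round(1.0 + 0.1 * i, 1) for i in range(11)]
    table = alpha_scan(fig_params, grid)
    pi_d = table["pi_D"].to_numpy()
    assert np.all(np.diff(pi_d) <= 1e-12)  # non-increasing along the grid


def test_alpha_scan_single_point(fig_params):
    table = alpha_scan(fig_params, [1.5])
    assert len(table) == 1


def test_alpha_scan_rejects_nonpositive_alpha(fig_params):
    with pytest.raises(ValueError):
        alpha_scan(fig_params, [1.0, -0.5])
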