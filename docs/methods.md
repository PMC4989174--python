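# Methods

## Model

A well-mixed population of `M` individuals holds three heritable
strategies: cooperators (C), defectors (D) and punishers (P). Each
period, `N` individuals are drawn without replacement into one public
goods game. Contributors (C and P) each pay `c`; a group with
`n = x + z` contributors produces `c * r * n**alpha` (with `0**alpha`
defined as 0), shared equally among all `N` members regardless of
contribution. Each punisher fines every defector in its group by
`delta`, paying `gamma` per defector. Group payoffs are therefore, with
`share = c * r * (x + z)**alpha / N`:

| strategy  | payoff                      |
|-----------|-----------------------------|
| cooperator| `share - c`                 |
| defector  | `share - delta * z`         |
| punisher  | `share - c - gamma * y`     |

so `P_x - P_z = gamma * y` exactly (the second-order free-riding
advantage) and `P_x - P_y = delta * z - c` (punishment deters defection
iff `delta * z > c`). Payoffs may be negative; the exponential fitness
map `F = exp(omega * P)` keeps fitness positive for any payoff sign,
which is why it is used instead of the linear `1 - omega + omega * P`.

Defector productivity is fixed at zero (no `beta` exponent), and
strategies are discrete; there is no population structure, no additional
strategy types, and no anti-social punishment.

## Rare-mutation analysis (`scalepgg.analytic`)

When `mu -> 0` the population contains at most two types at any time, so
long-run behaviour reduces to a Markov chain over the three homogeneous
states. For a pairwise population with `m_i` mutants of type i among
residents j:

* **Expected payoffs.** The focal player is guaranteed a group slot; its
  `N - 1` co-players are hypergeometric over the remaining `M - 1`
  individuals. This focal-conditioned form is standard for
  frequency-dependent Moran analyses and is required for the payoff to
  be conditional on the focal's own type. (The alternative — averaging
  over participation so that non-participants contribute zeros to the
  expectation — was examined and discarded: it compresses effective
  selection by `N / M` and erases the defector dominance at constant
  returns that both engines otherwise agree on.)
* **Transition rates.** `T+ = [m_i F_i / (m_i F_i + m_j F_j)] (m_j / M)`
  and symmetrically for `T-`, with `F = exp(omega * expected payoff)`.
  The ratio collapses to `theta = T-/T+ = F_j / F_i`.
* **Fixation.** `rho_ij = 1 / (1 + sum_{k=1}^{M-1} prod_{l=1}^{k}
  theta_l)`. Products are accumulated as sums of `log theta` and the
  outer sum with log-sum-exp, so the result stays finite at `omega = 5`,
  `M = 1000`, where the partial products span thousands of orders of
  magnitude. A linear-scale probability below the double-precision range
  is floored at the smallest positive float so the embedded chain never
  gains a spurious exactly-absorbing zero; `log_fixation_probability`
  exposes the exact magnitude.
* **Embedded chain.** From a homogeneous state j, each of the two
  possible mutant types is taken to arise with probability 1/2, giving
  off-diagonal entries `rho_ij / 2`. The uniform 1/2 factor leaves the
  stationary distribution unchanged; it only sets the chain's time
  scale.
* **Stationary distribution.** Computed twice — as the eigenvector of
  the transposed matrix with eigenvalue nearest 1, and by solving the
  balance equations with the normalization row substituted — and the two
  must agree within 1e-10, otherwise the chain is rejected as
  degenerate. The eigen route selects the eigenvalue closest to 1,
  normalizes by the component sum, flips sign if needed, and rejects
  components below -1e-9.

Correctness anchors in the test suite: neutral fixation equals `1/M`
(checked at `omega = 1e-8` to 1e-6 relative); the ratio-product formula
agrees with a direct linear solve of the absorbing birth–death chain to
1e-10 for `M <= 20`; with `delta = gamma = 0` cooperators and punishers
are payoff-identical and their stationary probabilities coincide to
1e-10.

## Agent-based simulator (`scalepgg.simulate`)

The simulator follows the per-period pipeline literally: sample one
group (multivariate hypergeometric over current counts), pay only the
sampled individuals (everyone else earns 0, hence baseline fitness 1),
then perform one birth–death event. Reproduction uses the genetic-pool
rule: conceptually every individual spawns an offspring with probability
proportional to its fitness and one pool member replaces a uniformly
chosen individual. Because payoffs within a period are equal within each
(strategy, sampled/unsampled) class, this is distributionally identical
to a single type-level draw with probability proportional to each type's
summed fitness mass — the implementation used in the hot loop; the
literal materialized pool is kept behind a `literal_pool` flag and the
two are checked against each other statistically. The newborn mutates to
one of the two other strategies, chosen uniformly, with probability
`mu`; mutation applies to the newborn only (a per-capita sweep would
inflate the effective mutation rate `M`-fold).

Determinism: one `numpy` generator per run, seeded from the
configuration. Sweep replicates derive independent seeds via
`SeedSequence([base_seed, grid_index, replicate_index])`. Identical
configuration and seed reproduce traces bit for bit.

Defaults: `burn_in = None` means 10% of periods; the figure-reproduction
recipes pass `burn_in = 0` so their averages cover the full run. Trace recording every period; recipes thin to every 10th period for
file size only.

## Experiments and chosen problem sizes

* `fig2`: analytic scan, `M=100, N=5, c=1, r=3, delta=1, gamma=0.3,
  omega=0.1`, alpha 1.0–2.0 step 0.1 (step matching the granularity at
  which the thresholds are quoted).
* `fig3a/b`: one 100,000-period trace at `omega=0.5, mu=0.001` from
  composition (30, 40, 30), alpha 1.0 vs 1.8.
* `fig4_a..i`: sweeps of alpha (from each monomorphic start), r, c,
  delta, gamma, omega, mu; 20 replicates x 100,000 periods at full
  scale. The non-alpha grids are package choices bracketing each
  baseline value. The r sweep runs at `alpha = 1.0` (its threshold
  effect mirrors alpha's and is only visible from the constant-returns
  baseline); the remaining sweeps run at `alpha = 1.8`.
* Acceptance sweep: alpha 1.0–1.5 step 0.1, 6 replicates x 40,000
  periods, burn-in 0 — a scaled version of the full sweep that keeps the
  replicated Monte Carlo average stable while remaining cheap.

## What the generator emulates, and what it does not

All experiments are self-generating: the model itself is the data
source, and the baseline parameter values above are the study
conditions. The simulator emulates demographic stochasticity (finite-`M`
drift), sampling noise from one game per period, and rare strategy
exploration. It does not emulate spatial or network structure, assortment,
reputation, or payoff accumulation across periods — so passing tests
demonstrate the logic of the increasing-returns mechanism under
well-mixed Moran dynamics, not its robustness in structured populations.

Replicate-to-replicate variance of the long-run frequencies is large by
the nature of the process: runs sojourn near homogeneous states for long
stretches, so a 40,000-period average is dominated by which regimes the
run happened to visit. Threshold locations extracted from sweep grids
are therefore reported to one grid step.

The two engines are close relatives, not the same process. The analytic
chain gives every individual the *expected* payoff of its type each
period; the simulator pays only the one sampled group its *realized*
payoffs. Outside the weak-selection limit this extra payoff noise
systematically favours punishers relative to the rare-mutation
prediction — the simulated punisher/defector crossover (~1.1–1.2) sits
below the analytic one (1.3–1.4) for exactly this reason, so the two
engines' stationary rankings should not be expected to coincide
state-for-state at moderate or strong selection.

## Numerical choices

* Hypergeometric masses via log-gamma; normalization error stays below
  1e-9 up to `M = 10^4`.
* `0**alpha = 0` for all `alpha > 0` (the all-defector group produces
  nothing, without domain errors).
* Fitness ratios in transition rates are computed with a max-shift
  before exponentiation to avoid overflow at strong selection.
* Group payoffs inside the simulation loop are cached per composition
  (at most `binomial(N + 2, 2)` distinct compositions per run).
* Reducible or periodic embedded chains (e.g. the identity matrix) are
  rejected rather than silently returning one of many stationary laws.

## Known limitations

* The embedded-chain API is fixed to three strategies; the internal
  machinery would generalize but is not exposed.
* Finite-`mu` corrections to the analytic stationary law are out of
  scope; finite mutation is handled only by the simulator.
* At `alpha` near the simulated crossover (~1.1–1.2) the sweep's
  threshold estimate can shift by one grid step between seed sets; the
  analytic thresholds are exact.
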