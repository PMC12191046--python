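# Methods

`srct` implements the Bayesian machinery a statistician needs to plan and
analyse a small randomized comparative trial (SRCT): 2–4 arms, roughly 10–30
patients per arm, binary early response (Res) and severe toxicity (Tox)
endpoints, optional exponential event-time summaries. This note records the
models, the numerical choices, and the places where the design was genuinely
open.

## Models and assumptions

**Beta-binomial conjugacy.** Each arm's event probability θ carries a
beta(a, b) prior; X events in n evaluated patients give the posterior
beta(a + X, b + n − X). Its mean is the shrinkage-weighted average
w·(X/n) + (1 − w)·a/(a + b) with w = n/(n + a + b), so the prior acts like
ESS = a + b phantom patients. Operational priors are elicited as a
(mean, ESS) pair with ESS = 1 (at most 2) so that even small trials dominate
the prior; `prior_from_mean` rejects degenerate means of exactly 0 or 1
because a beta prior with mass at an endpoint has no conjugate
interpretation and the elicitation convention always uses interior means.

**Independent arms.** Randomized arms are modeled as statistically
independent with separate priors; nothing is borrowed across arms. Every
comparison below relies on that independence.

**Difference of two betas.** The treatment effect θ_E − θ_S has no
closed-form distribution. Its CDF is computed by adaptive quadrature
(`scipy.integrate.quad`, absolute tolerance 1e−10, explicit break points
where v + d crosses the support edges, so integrable endpoint singularities
of beta densities with a < 1 or b < 1 are handled):

    Pr(θ_E − θ_S ≤ d) = ∫₀¹ f_S(v) F_E(clip(v + d, 0, 1)) dv.

Equal-tailed credible intervals for the difference invert this CDF with
Brent root-finding on [−1, 1] (xtol 1e−9). The improvement probability is
Pr(θ_E > θ_S + δ | data) = 1 − CDF(δ); δ = 0.15 and 0.20 are offered as
defaults because those are the margins conventionally treated as clinically
meaningful. Quadrature, not Monte Carlo, is the primary method: it is
deterministic and reproducible. Monte Carlo appears only as an independent
test oracle and in post-stratified intervals, always behind an explicit
seed.

**Credible intervals are equal-tailed**, i.e. quantile-based, not HPD.
Single-parameter intervals come straight from the beta quantile function
(inverse regularized incomplete beta, scipy's `beta.ppf`). HPD intervals
are deliberately not offered; all reference computations in this package
use equal tails and the two conventions differ for skewed posteriors.

**Exponential-gamma event times.** With an exponential hazard λ ~
gamma(shape, rate), k events over total follow-up T give the posterior
gamma(shape + k, rate + T). The median event time ln 2/λ is a decreasing
transform of λ, so its interval endpoints are the hazard quantiles with
upper and lower swapped (`median_time_interval`).

**Post-stratification.** When an observed imbalance warrants it, the
between-arm difference is computed within each stratum and averaged with
user-supplied stratum weights (weights must sum to 1 within 1e−9). The
point estimate is exact by linearity; the interval is the equal-tailed
quantile range of 10⁶ seeded Monte-Carlo draws of the weighted difference.
Strata may mix beta posteriors with known probabilities; known rates enter
as constants.

## Monitoring rules and boundaries

A safety rule stops an arm when Pr(θ_Tox > θ* | data) > c, where θ* is the
largest acceptable toxicity probability; the comparator variant replaces
the fixed θ* with a highly informative beta posterior (e.g. beta(200, 800)
centred at 0.20) and stops when Pr(θ_E > θ_S | data) > c, evaluated with
the same difference quadrature at δ = 0. Futility rules mirror the
construction below a smallest acceptable response rate. Conventions:

- **Strict inequality.** A posterior probability exactly equal to the
  cutoff does not stop. This matters only on measure-zero configurations
  but fixes the integer boundaries unambiguously.
- **Looks are interim only.** The final per-arm analysis is not a stopping
  look; a design wanting a final-look rule lists it explicitly.
- **Default rule prior.** When a design does not state one, the rule prior
  is beta(θ*, 1 − θ*) — mean θ*, ESS 1. With this convention the reference
  fixed-limit rule (θ* = 0.30, c = 0.90, looks 4/8/12 of 16) reproduces the
  protocol triggers 3/4, 5/8, 6/12, and the comparator rule (beta(0.20,
  0.80) prior, beta(200, 800) comparator, c = 0.90, looks 8/16 of 24)
  reproduces 4/8, 6/16; both are locked in tests.
- **Cutoff families.** Constant c, or α(n/N)^β for cutoffs that tighten
  with information; the evaluated value must stay inside (0, 1).

Because the posterior criterion is monotone in the event count, each rule
is exactly equivalent to integer trigger counts per look, derived by
enumeration (`boundary_table`) and verified against direct rule evaluation
for every possible count.

## Operating characteristics

**Exact single-arm OCs.** The stop-time distribution of one monitored arm
under a true event probability is computed by a dynamic program over
(look, cumulative event count) with binomial cohort increments — exact to
floating precision, no simulation error. Pstop is the total interim stop
mass; sample-size quartiles are the smallest reachable per-arm sizes whose
cumulative stop-time mass reaches 0.25/0.50/0.75 (mass at n_max includes
arms never stopped). The DP is validated against exhaustive enumeration of
all 2^n outcome sequences at small n and against a vectorized 10⁵-arm
simulator.

Note one published reference table this package intentionally corrects: for
the fixed-limit rule above at true toxicity 0.60, exact computation gives
quartiles (4, 8, 12), and indeed any distribution with Pstop = 0.86 must
have its upper quartile by the last interim look; at true toxicity 0.40 the
cumulative stop mass at 8 patients is 0.24998, a razor edge that simulation
rounding can tip either way. The exact values are what the code (and its
tests) report.

**Full-trial simulation.** Multi-arm behavior — block randomization,
enrichment, final selection — is simulated because arm interactions break
independence. Mechanics: patients accrue following a permuted-block plan;
outcomes are treated as immediately evaluable (no accrual or assessment
lag); each arm's rules fire when its evaluated count reaches a scheduled
look. When an arm stops, the remaining positions are re-blocked over the
surviving arms (enrichment) so the planned total N is preserved whenever at
least one experimental arm survives; if every experimental arm stops, the
trial terminates with nothing selected. At trial end the surviving
experimental arm with the largest posterior mean response rate (beta(0.5,
0.5) selection prior by default) is selected; ties break toward the
earliest-listed arm, i.e. the lowest dose, which is the safety-conservative
choice. A selection margin δ > 0, when configured, additionally requires
the winner's posterior mean to exceed the reference's by δ. Reproducibility
uses one root seed with per-simulation streams derived from (seed, sim
index), so results do not depend on batching.

**Cutoff calibration.** `calibrate_cutoff` scans a grid of cutoff
specifications, computes each candidate's exact Pstop at θ* (acceptable)
and θ** (unacceptable), keeps those with Pstop(θ*) at or below the
requested cap, and returns the one maximizing Pstop(θ**), breaking ties
toward the larger cutoff (fewer stops at an acceptable rate). An
infeasible cap returns the closest candidate flagged rather than failing.

## Randomization

Blocks are independent uniform random permutations of the balanced multiset
(each arm block_size/K times), generated up-front for the whole plan. The
uniform-permutation mechanism is the natural reading of "randomly
scrambled" and is verified by a frequency test over all 90 arrangements of
a 3-arm block of 6. Stratified plans draw independent child seeds via
`numpy.random.SeedSequence.spawn`. Enrichment replanning keeps the original
per-arm quota per block (block size scales down with the surviving arm
count) and truncates the final partial block so total planned N is
unchanged; whether block size should shrink after an arm drop is not
standardized anywhere, and scaling to the survivor count is this package's
choice because it preserves the balance guarantee at the same per-arm
cadence.

## Synthetic data

`generate_trial_dataset` emits one simulated trial realization at patient
level (id, block, arm, binary tox and res draws at the scenario's true
rates, truncated at any triggered stop). It emulates a monitored,
block-randomized SRCT under the stated design; it does not model accrual
times, evaluation lag, missing outcomes, or covariate-driven heterogeneity,
so passing tests demonstrate correctness of the design arithmetic, not
robustness to those real-data features.

## Problem sizes used in the reference computations

The exact DP and boundary derivations are closed-form-scale and run in
milliseconds. Simulation sizes were chosen once as standard practice for
their role: 10⁵ arms for single-arm simulation cross-checks of the exact DP
(Monte-Carlo SE ≈ 0.0015 on a probability near 0.1), 10⁶ draws for
Monte-Carlo oracles of quadrature quantities (SE ≤ 5e−4), and 2–3 × 10³
full-trial simulations in tests with 3-standard-error tolerances.

## Known limitations

- No non-conjugate priors, no MCMC, no covariate regression or
  multiplicity adjustment across pairwise comparisons.
- No predictive-probability futility, frequentist alpha-spending
  boundaries, or joint Res/Tox utility rules; endpoints are monitored
  marginally.
- The trial simulator has no time-to-event outcomes and no
  outcome-adaptive randomization; unequal allocation ratios are not
  supported.
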