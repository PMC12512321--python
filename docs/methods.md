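# Methods

## The simulated trial

`adaptsim` models a two-arm, parallel-group superiority trial with a
binary outcome and one pre-planned interim analysis triggered by event
count. A simulated trial is assembled in five stages, each an
independently testable function, and the whole pipeline is a
deterministic function of `(design, scenario, seed)`.

**Randomisation.** Participants are allocated by permuted blocks: each
block of `block_size` contains exactly `allocation = (n_control,
n_treatment)` assignments in uniformly random order. Blocks are permuted
by ranking per-block uniform draws, which is distributionally identical
to any correct shuffle; whole blocks are generated and the sequence
truncated to `n`, so a trailing partial block is a truncated permuted
block (untestable against the default design, where 584 is divisible
by 4, hence documented here as the package's choice).

**Accrual.** Recruitment times are the order statistics of `n`
independent Uniform(0, `recruit_period`) draws — constant expected
accrual with realistic sampling noise. Multi-site ramp-up/ramp-down can
be injected through the `sampler` hook of `simulate_accrual`; only the
uniform sampler ships, and it is what every shipped result uses.

**Outcomes.** Each participant's event indicator is an independent
Bernoulli draw with probability `p0` (control) or `p1` (treatment) from
the active scenario. The outcome is treated as observed at the moment of
recruitment (zero lag); an outcome-lag parameter is a deliberate
extension point, not implemented.

**Interim selection.** Rows are ordered by accrual time, so the data
available when the trigger-th event occurs is exactly the prefix through
the participant contributing that event (that participant included).
If a dataset never reaches the trigger, the interim is skipped: interim
statistics are recorded as missing, `interim_stop = 0`, and only the
final analysis decides. Under the default design (trigger 20, expected
events ≥ 40) this is a vanishingly rare edge case, but the engine must
behave sensibly there.

**Analysis and decisions.** The primary analysis is a logistic
regression of outcome on the treatment indicator. With one binary
covariate the maximum-likelihood fit is closed-form in the 2×2 table
(treatment events `a`, non-events `b`; control events `c`, non-events
`d`):

    log OR = ln(ad / bc),  SE = sqrt(1/a + 1/b + 1/c + 1/d)

with Wald two-sided p-value and CI `exp(log OR ± z·SE)`. The closed form
is used in production because it is exactly the estimator an
iteratively-reweighted-least-squares fit reports (the test suite holds
the two routes to 1e-6 agreement on the log-odds scale over 1,000 random
tables) and is orders of magnitude faster inside a 5,000-replicate loop.
Wald — rather than likelihood-ratio or score — inference is used so that
the p-value and CI come from the same machinery a standard glm summary
prints.

Efficacy is declared when the p-value is **strictly** below the spent
threshold (`alpha_interim`, then `alpha_final`). With continuous test
statistics the boundary event has probability zero, so nothing turns on
strict versus non-strict. Both analyses are always computed, even for
trials that cross the interim boundary (post-processing design): this is
what makes the flip-flop probability — interim success not confirmed on
the complete data — observable, and lets alternative thresholds be
evaluated against stored results without regenerating data.

**Degenerate tables.** A 2×2 table with a zero cell separates the
logistic fit: the MLE diverges and the Wald SE is unbounded, so an IRLS
fit would report an enormous SE and p ≈ 1. The closed form encodes that
limit directly: `degenerate = True`, p-value 1, no finite OR or CI. A
degenerate trial can therefore never stop for efficacy, and degenerate
odds ratios are excluded (with a reported exclusion count) from
summary means. At the default event rates a zero cell is vanishingly
rare at the final analysis.

## Parameters and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `n` | 584 | maximum sample size; 292/arm gives 80% power for 10% vs 4% at two-sided 0.045 |
| `recruit_period` | 928 days | uniform accrual window |
| `events_at_interim` | 20 | interim trigger: half the expected events under the null rate |
| `alpha_interim` | 0.005 | interim efficacy threshold (spent conservatively) |
| `alpha_final` | 0.045 | final efficacy threshold; 0.005 + 0.045 spends ≈ the conventional 0.05 |
| `block_size`, `allocation` | 4, (2, 2) | 1:1 permuted blocks of four |
| `ci_level` | 0.95 | CI level for all interval estimates |

Scenarios are named `(p0, p1)` pairs; the built-in grid holds the
control rate at 10% and varies the treatment rate: 0.10 (null), 0.04
(as powered), 0.06 (smaller difference), 0.03 (larger difference).

## Seeding and reproducibility

A master seed drives a dedicated generator whose single vectorised draw
yields one integer seed per trial (and, in the scenario grid, one master
seed per scenario). Each trial then consumes a fresh generator in a
fixed, documented order — allocation permutations, accrual times,
outcomes — so:

- any stored trial is replayable in isolation from its recorded seed;
- results are invariant to execution order or parallel chunking;
- a run manifest (design, scenario, `n_sims`, master seed, package
  version) reproduces every output file bit-for-bit.

Per-trial seeds are drawn from [0, 2³¹), small enough for any downstream
tool that expects 32-bit seeds.

## Sample-size calculation

`two_proportion_n` implements the pooled-variance ("chi-square based")
normal approximation for two independent proportions, ceiling-rounded
per arm. This variant is the one consistent with analysing the trial by
a Pearson-type test, and it reproduces the 292/arm the default design is
built on. With `continuity_correction=True` the Fleiss adjustment
inflates the uncorrected real-valued n before rounding; the test suite
cross-checks the corrected n against an exact enumeration of the
continuity-corrected chi-square test's power over all binomial outcome
pairs (the Fleiss n attains the target power and over-covers the exact
minimal n by a handful of participants). Commercial tools apply their
own rounding conventions to the corrected calculation, so
bit-compatibility with any particular product is out of scope.
`odds_ratio_from_props` converts an event-probability pair to the
implied odds ratio (0.10, 0.04 → 0.375).

## What the generator does and does not emulate

The generator reproduces the stochastic structure the design analysis
relies on: balanced blocked allocation, noisy but stationary accrual,
outcome-accrual independence, and binomial outcome noise. It omits, by
design: loss to follow-up and missing outcomes, outcome lag, site-level
accrual heterogeneity, stratified randomisation, and any secondary
endpoints. Passing tests therefore demonstrate the *design arithmetic* —
error rates, expected savings from the interim — under idealised
conduct, not robustness to the operational frictions of a real trial;
those require extending the relevant building block.

## Numerical and design choices

- Quartiles in summary tables use linear interpolation of order
  statistics ("type 7", the numpy/pandas/R default); alternative
  quantile rules differ by O(1/n_sims) and are immaterial at 5,000
  replicates.
- Missing values (unreached interims, degenerate fits) are excluded from
  summaries with an explicit `n_missing`/`n_excluded` count, never
  silently dropped.
- Probability-valued indicator variables are summarised with the full
  six statistics like every other variable, keeping the summary-table
  schema identical across variables even though only the mean is
  interpretable.
- Accrual ties (probability zero) keep draw order via a stable sort.
- Monte-Carlo sizes: shipped results and the end-to-end tests use 5,000
  trials per scenario, matching the replication count the reference
  operating characteristics were computed at (binomial SE ≈ 0.006 for a
  probability near 0.80); the power-monotonicity check uses 1,000 trials
  per scenario, ample for orderings separated by many standard errors.

## Limitations

- Efficacy-only stopping: no futility boundary, no sample-size
  re-estimation, single interim only (the selection function is the
  place to generalise).
- The closed-form analysis covers exactly the unadjusted two-arm
  comparison; covariate-adjusted analyses would need a genuine IRLS fit
  in the loop.
- Operating characteristics inherit Monte-Carlo error; quantities near
  0 or 1 (e.g. the flip-flop probability) need far more than 5,000
  replicates for a second significant digit.
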