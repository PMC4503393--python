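# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pvasim`.  It is the design record; empirical numbers
quoted here are ones the test suite or `scripts/acceptance.py` compute.

## Life histories and the projection matrix

A life history is a vector of per-class annual survival probabilities
`s_1 … s_K`; the terminal class is a composite ("K+ years old") with
self-loop survival `s_K`.  The Leslie matrix carries a single shared
fecundity `f` across the whole top row (age at first reproduction is
one year), `s_1 … s_{K−1}` on the sub-diagonal, and `s_K` in the
bottom-right corner.  Presets:

| name | classes | survivals (last = self-loop) | PE_CV grid |
|---|---|---|---|
| `hypothetical` | 10 | 0.5 × 10 | 0, 0.1, 0.3, 0.5 |
| `t_lamproides` | 5 | 0.4, 0.5, 0.8, 0.75, 0.7 | 0, 0.1, 0.3, 0.45 |

The snail grid stops at 0.45 because a beta distribution on [0, 1]
cannot carry CV 0.5 at mean 0.8 (`sd² = 0.16 ≥ μ(1−μ) = 0.16`); config
validation enforces this bound for any life history.

**Fecundity back-calculation.** `f` is the unique nonnegative root of
`ρ(A(f)) = λ`, found by Brent's method on `[0, λ]` (expanded upward if
needed) with tolerance ~1e−12; `ρ` is strictly increasing in `f`, and
targets at or below the fecundity-free spectral radius raise an explicit
infeasibility error.  For the hypothetical structure the renewal
equation collapses to a geometric series giving the closed form
`f = λ − s`, which the solver reproduces to 1e−10.

**Generation time.** The package reports the cohort generation time —
the mean age of the mothers of a cohort's offspring,
`T = Σ x f l_x / Σ f l_x`, with the composite class expanded as a
geometric tail (`l_x` decaying by `s_K` beyond age `K`).  The definition
was genuinely open; the growth-rate-discounted variant (weights
`λ^{−x}`, the mean age of mothers at the stable age distribution) is
available via `discounted=True` but was not adopted as the default
because at `λ = 0.9` it pushes the snail's three-generation window past
ten years, which would contradict the use of the fixed ten-year
projection horizon for every parameterization.  With the cohort
definition, `3T < 10` years holds for all eight (life history × λ)
combinations.

## Truth model

`n_{t+1} = A_t n_t` for 60 annual steps from the stable age distribution
scaled to `n0 = 1e9`.  Each year, every survival (ascending class order,
composite last) and then the fecundity is drawn independently:

* survivals: beta on [0, 1], moment-matched (`α = μν`, `β = (1−μ)ν`,
  `ν = μ(1−μ)/σ² − 1`) with `σ = PE_CV·μ`;
* fecundity: stretched beta on [0, 1000], i.e. a moment-matched standard
  beta linearly rescaled — moment matching is affine-invariant.

`PE_CV = 0` is treated as a point mass (the mean matrix), not a limiting
beta, avoiding degenerate shape parameters.  Abundances are real-valued:
with 10⁹ individuals demographic stochasticity is negligible and is
deliberately not modelled, so no integer rounding is applied.  Draws are
not truncated or re-drawn; the beta supports already respect the [0, 1]
bounds.

The geometric-mean growth rate over years 50–60 and the signed percent
decline `100(N_50 − N_60)/N_50` are linked by
`decline = 100(1 − g^{10})`; negative declines are growth.

## Observation model

Each age-year abundance is independently perturbed to
`max(0, Normal(n, ME_CV·n))`.  Negative draws are clamped rather than
re-drawn — at the study's abundance scales a negative draw requires a
3.3σ excursion (probability ~4e−4 at ME_CV 0.3), so the choice is
immaterial, but it is the simpler contract.  Observed totals are always
the sum of the perturbed classes; the total is never perturbed
separately.  The estimation window is the last `M` of the 50 history
years (years `50−M+1 … 50`), so windows of different lengths are nested.

## Estimators

Scalar: `M − 1` ratios of observed totals, never censored or truncated.
Matrix: the estimated model has `K − 1` classes, the last a composite of
true classes `K−1` and `K`.  Cohort ratios with the printed formulas;
survival estimates > 1 (or with a zero denominator) are censored —
excluded from the resampling pool and counted per class.  Fecundity and
scalar growth estimates are never censored.

Two points were open and are exposed as switches:

* **Fecundity denominator** (`fecundity_denominator`): the printed
  formula sums observed classes `1 … K−1`, which can be read as
  excluding the terminal observed class or as the total population once
  the composite pooling is taken into account.  The default is the
  pooled total.  The distinction is negligible for the hypothetical life
  history (terminal class ≈ 0.1% of the population) but decisive for the
  snail, whose terminal class is large: excluding it roughly doubles
  estimated fecundity and produces runaway projected growth inconsistent
  with every reported pattern, so the pooled-total reading is clearly
  correct.
* **Empty pools** (`empty_pool_fallback`): if every estimate for one
  survival rate was censored (possible only at very short windows), the
  default restores that pool's censored values capped at 1.0 and records
  the event (`fallback_classes`, per-scenario `fallback_events`);
  `"error"` aborts instead.  At `M = 5` with typical censoring rates the
  event probability is ~1e−3 per replicate.

With no process and no measurement error both estimators reproduce the
true dynamics exactly and the end-to-end decline difference is zero to
floating-point roundoff (the suite asserts |diff| < 1e−9 percentage
points across the full zero-error grid).  Note the composite-class
ratio estimates the stable-age-weighted mix of the penultimate
transition and the self-loop survival — identical to both only when
they coincide, but always self-consistent for projecting the aggregated
class.

## Projection

Ten years, 1000 trajectories per estimated model (paper scale).  Every
time step of every trajectory draws one value per rate pool,
independently across rates, trajectories and years, assembles the
estimated-class Leslie matrix and advances the age vector; the initial
vector is the final observed census aggregated onto the estimated
classes.  The per-trajectory score is the signed percent decline of the
total; the model's point prediction is the sample median (midpoint
convention for even counts).

Censoring makes the retained survival pools systematically low, so
matrix projections under high measurement error realize lower growth
than the truth and over-estimate declines — the central bias mechanism,
visible in the per-scenario `mean_censored_fraction` the summaries log.

## Scenario orchestration and reproducibility

`diff = true − estimated` (over-estimated declines therefore appear
negative).  Precision = 1/IQR width of the diffs (stored as missing when
the width is exactly zero), bias = their median.  Seeds: every stage of
every replicate gets a named `SeedSequence` keyed on (master seed, life
history, λ, PE_CV, ME_CV, replicate, stage), with the window length
entering only the projection streams.  Replicate `i` therefore reuses
the same true and observed series across window lengths — nested
windows, as in a real monitoring programme, which also sharpens
cross-`M` precision comparisons — while results are independent of
execution order and reproducible bit-for-bit.

## Problem sizes

Defaults follow the study design (1000 true replicates × 1000
trajectories per scenario).  The test suite and the acceptance script
run the high-error comparison scenario at 200 × 200, which resolves the
IQR-reduction quantities to within a few percentage points while keeping
a desk-scale footprint; replication counts are first-class configuration.

## Known limitations

* Density dependence, demographic stochasticity, vital-rate
  correlations, and catastrophes are out of scope, as is state-space
  estimation that could separate measurement from process error.
* The IQR-reduction quantities at 200 replicates carry Monte-Carlo noise
  of several percentage points; seed-to-seed spread of an IQR ratio is
  inherently large.
* The synthetic censuses are idealized: every age class is observed
  every year with known, age-independent relative error and no detection
  model (no Poisson/binomial sampling).  Passing tests demonstrate the
  estimators' behaviour under exactly these conditions, not under real
  survey designs with structured observation error.
* The "populations never fell below 1000 individuals in the history
  years" regularity holds marginally at the most extreme
  parameterization (hypothetical, λ = 0.9, PE_CV = 0.5): about one
  replicate per thousand dips below 1000 (to ~500–1000 individuals).
  It is a high-probability regularity of the model, not a theorem.
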