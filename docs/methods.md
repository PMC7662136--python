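# Methods

## Model structure

The package compares total years of life lost (YLL) attributable to
COVID-19 in early 2020 under two scenarios.

**Closed schools.** Two components, summed per Monte Carlo draw:

1. *Direct YLL.* Age-banded death counts per sex, each band carrying the
   remaining life expectancy at its midpoint age; direct YLL is
   `Σ deaths × e(midpoint)`. Reported deaths understate true COVID-19
   mortality, so the total is multiplied by an undercount ratio drawn from
   `PERT(min 1, mode 1.22, max 2.44)` — minimum 1 because excess deaths
   are assumed non-negative, mode from an excess-mortality comparison,
   maximum twice the mode.
2. *Education-mediated YLL.* A two-stage chain. Stage 1: each 10 missed
   school days reduce final educational attainment by a sex-specific
   coefficient (boys 0.0262 years, SE 0.0064; girls 0.0217, SE 0.0062),
   drawn truncated-normal with a lower bound of 0 (closure cannot raise
   attainment). Stage 2: each year of attained education multiplies annual
   mortality by a relative risk RR drawn `Normal(0.75, sd 0.0765)`; losing
   `L` years multiplies every annual death probability from the child's
   current age onward by `RR^(−L)`. The child's YLL is the drop in
   (discounted) remaining life expectancy of the sex-specific life table
   under the scaled hazard.

**Open schools.** The same corrected direct-YLL draw multiplied by a
schools-open mortality ratio drawn `PERT(min 1, mode 1.93, max 2.85)`:
maximum from a published estimate of deaths prevented by school closure,
minimum 1 reflecting evidence that young children transmit little, mode
the average of the two published estimates. No education loss.

The decision quantity is the paired exceedance probability
`P(direct + education > direct × ratio)`, reported per discount rate.

## Parameters that matter

| parameter | default | units / rationale |
|---|---|---|
| attainment coefficients | 0.0262 / 0.0217 (SE 0.0064 / 0.0062) | years of final attainment per 10 missed school days, by sex; quasi-experimental strike-exposure estimates |
| education–mortality RR | 0.75 (95% CI 0.60–0.90) | per additional attainment year; sd = (0.90−0.60)/3.92 = 0.0765, the only reading consistent with a symmetric normal CI |
| undercount ratio | PERT(1, 1.22, 2.44) | dimensionless multiplier on direct YLL |
| mortality ratio | PERT(1, 1.93, 2.85) | schools-open vs closed death-rate ratio |
| discount rates | 0, 0.5%, 3% per annum | applied to education-mediated life-years only; direct deaths occurred in 2020 |
| max age of death | 85 | terminal age of the YLL arithmetic (see below) |
| draws | 100,000 default | single-CPU cost is dominated by the population simulation (~0.6 ms/draw) |

PERT draws use the classic shape (modal weight 4): a beta on
[min, max] with `α = 1 + 4(mode−min)/range`, `β = 1 + 4(max−mode)/range`.
Summaries are medians with equal-tailed percentile intervals (95% default;
the level is a parameter). One master seed spawns a named substream per
parameter, so changing the draw count of one never perturbs another.

## Life-table arithmetic

Tables hold annual death probabilities `q(x)` on integer ages 0..ω with
`q(ω) = 1`. Expectancy uses the curtate-plus-half-year convention
`e(x) = Σ_{t≥1} S(x+t)/S(x) + ½`; discounting weights the year survived at
`t` by `(1+r)^(−t)` and leaves the half year within the year of death
undiscounted. The education hazard multiplier scales `q` proportionally,
`q'(x) = min(1, m·q(x))`; for `q ≤ 0.1` and `m ≤ 1.5` this differs from
scaling the continuous hazard by under 1%.

**Reconstruction from anchors.** Full tables are rebuilt from eleven
printed (age, e(x)) anchors per sex. The default method interpolates the
log integrated hazard piecewise-linearly between anchor ages (extrapolating
the last slope to ω = 100) and solves the node values so the table's e(x)
reproduces every anchor (< 0.01 y); the age-0 anchor then pins the infant
death probability exactly via `e(0) = ½ + (1−q₀)(e(1)+½)`. A 3-parameter
Gompertz–Makeham fit (`μ(x) = A + B e^{Cx}`) is available as a smooth
alternative; on observed US anchors it misfits by up to ~0.33 y — infant
mortality and old-age deceleration are not Gompertz–Makeham shaped —
which is why it is not the default.

**Maximum age of death.** The YLL arithmetic treats 85 as the maximum age
of death (the death-band table's top band, and the model's stated terminal
assumption), implemented by truncating the table at ω = 85 for the
education stage. This matters: a lifelong hazard multiplier acts mostly at
old ages, so capping at 85 moderates the per-child loss (≈0.36 y for an
8-year-old boy at the central parameters versus ≈0.50 y uncapped) and is
what makes the per-child results consistent with the published central
values. Configurable via `ModelParams.max_age_of_death`.

**Onset age.** The multiplier applies from the child's current age by
default (`rr_from_age="child"`); `"adult"` defers it to age 18, which
changes undiscounted results by ~2%.

## Synthetic study conditions

The generator reproduces the study conditions exactly and deterministically
where totals are published: 24.2M public-school children aged 5–11
(11.4M White, 4.3M Hispanic, 3.6M Black, 4.9M Other; race totals exact by
largest-remainder rounding), 51.2% male, ages uniform across 5–11, states
weighted by a bundled share vector (any 51-vector is accepted). Per-state
closure days are drawn from a beta on [30, 85] days — a plausible range
for closures starting mid-March and running to the school-year end — with
shapes solved so the quartiles hit the published 48/54/62.5; sampling uses
randomized stratified inversion so the 51-state sample median and IQR stay
within ~1 day of the targets for every seed. Race-specific life tables
default to the sex-average tables (additive expectancy offsets are a
config hook) because only sex-average anchors are published.

Features of real data deliberately not emulated: actual state-by-state
closure orders, correlation between state size and closure length,
non-uniform age structure, race-specific mortality differences, and
within-state heterogeneity. Passing tests therefore validate the model
mechanics and the published aggregate conditions, not geographic detail.

The mean (13.7) and SD (2.1) of adult final attainment are carried as
metadata for reporting; the YLL model is a pure decrement model and never
consumes the baseline level.

## Numerical choices

* Population simulation shares one RR draw and one per-sex coefficient
  draw across all cells within an iteration (systematic parameter
  uncertainty, not per-child sampling noise), and shares each draw's
  adjusted survival curves across all discount rates.
* RR draws ≤ 0 are rejected (probability < 1e−21 at the defaults); draws
  above 1 are retained and produce small negative education YLL in ~0.06%
  of iterations.
* Degenerate inputs are exact: zero-SE coefficients, collapsed RR
  intervals and point-mass PERT triples reduce the whole pipeline to a
  deterministic, hand-checkable computation.
* The closed and open scenarios share the direct-YLL draw within an
  iteration (paired comparison); `paired=False` draws an independent
  undercount stream for the open branch.
* Default problem sizes: 100,000 draws for single-quantity Monte Carlo,
  20,000 for the population simulation in the bundled scripts — median
  standard errors are well under 1% of the reported values at those sizes.

## Known limitations

* The attainment-loss credible intervals are those of a truncated normal
  with the stated SEs; the published intervals for boys are wider and
  right-skewed in a way those SEs cannot produce, and no extra variance
  source is stated. This package reproduces the central values and flags
  the interval-width disagreement rather than guessing a distribution.
* The published discounting arithmetic is unstated. Discounting here runs
  from 2020 (the child's current age), which shrinks far-future losses
  harder than the published figures imply: at a 3% rate the education
  medians land ~20% below the published value and the closed-vs-open
  comparison drops below a coin flip (~0.39 versus the published 0.531).
  The 0% and 0.5% results, and every scenario-2 quantity, are unaffected.
* The education–mortality RR is consumed as a parameter; its meta-analytic
  derivation is out of scope.
* Period (not cohort) life tables: mortality improvement over the
  children's lifetimes is ignored, as are wage, quality-of-life and
  dropout-cascade effects — the model is deliberately a conservative,
  transparent decrement model.
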