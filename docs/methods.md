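# Methods

## Model structure and assumptions

The model is a deterministic expected-value cohort projection (a
decision tree with two health states: permanent OBPI present/absent,
no transitions). Each model year a fixed number of births occurs;
births covered by established training carry a training-age-dependent
injury probability, everyone else the baseline probability. The model
deliberately ignores demographic trend (births and coverage are fixed
across the horizon), the vaginal/caesarean birth mix (the baseline
probability is applied per birth), mortality (everyone survives the
horizon), and settlement timing (the injury cost is charged in the year
of birth).

Expected counts are carried at full floating precision; fractional
injuries are expectations, not people, and rounding is a display
concern only.

## Probability-decline schedule

The tabulated injury probabilities are **not** a single linear segment:
they are piecewise linear with anchors (0 y, 0.192‰), (4 y, 0.15‰),
(12 y, 0‰), evaluated at integer years and rounded **half-up to six
decimals** — this back-derives every tabulated cell (e.g. the
unrounded year-5 value is 0.13125‰, printed 0.000131). Floats are
pre-rounded to 12 decimals before quantising so binary representation
noise cannot flip a half-way case (the exact year-10 value 0.0000375
must round to 0.000038). An unrounded mode
(`schedule_round_decimals: null`) exists for sensitivity work and is
used automatically when the PSA rescales the schedule.

Indexing convention: a cohort listed with *k* established years
experiences schedule index *k* in model year 1 and advances one index
per year, saturating at zero from index 12 (so the 15-year cohort
contributes no injuries in any year). The alternative (*k*−1 / *k*+1)
conventions change the 30-year totals by roughly ±1%; the chosen
convention reproduces the published totals within 1% and is exposed
through the anchor configuration rather than hard-coded arithmetic.

## Costs

* Training: per-birth rates, first-year vs subsequent-year. All
  pre-existing cohorts pay the subsequent rate throughout; under
  nationwide rollout the newly enrolled births pay the first-year rate
  in model year 1 only. The two variants (full programme vs standalone
  shoulder-dystocia training) differ **only** in these rates; their
  clinical effect is identical by assumption.
* Injury: mean settled litigation claim (£127,418,372 / 376 claims =
  £338,879, rounded to the nearest pound) as a proxy for the lifetime
  cost of one permanent OBPI. Claims inflation (10%/yr) compounds from
  model year 1; the 3.5% annual discount is applied on top, giving a
  net cost growth of about 6.3%/yr. Both rates are plain config
  scalars, so alternative readings of how the personal-injury discount
  rate interacts with claims inflation are one-line changes.
* Currency is GBP throughout (2017 price year is metadata); any
  dollar presentation is display-only and never enters computation.

## QALYs

For the cohort born in model year *t*, with horizon *H* = 30 and
adulthood at 18: child years = min(18, H − t + 1) and adult years =
max(0, H − t + 1 − 18); the two partition the in-horizon lifespan
exactly. Affected adults accrue utility 0.56 per adult year, their
parents 0.80 per child year (one parent dyad per child, no
sibling/second-parent weighting); unaffected individuals and their
parents accrue the population norm 0.86, so scenario totals are
population-scale while incremental QALYs depend only on the utility
differences (0.30 per adult year, 0.06 per child year). The dyadic
QALY is defined as the exact sum of the adult and parental components.

QALY discounting defaults **on** (costs and outcomes discounted alike),
weighting each life-year by the discount factor of the calendar year in
which it is lived, standard cost-utility practice. An undiscounted mode
is first-class because the published QALY table is internally
consistent with a mix of conventions: our undiscounted adult gain is
446 against a printed 451, while the printed parental gain sits between
our discounted (593) and undiscounted (1,197) values. Absolute QALY
totals are therefore property-tested (additivity, linearity,
monotonicity), not value-matched.

## Incremental analysis

Deltas are nationwide minus current, so negative cost deltas are
savings. ICERs with a zero QALY delta are reported as undefined, never
a division error. Dominance requires strict signs (cheaper *and* more
effective); boundary cases (a zero delta) fall to the trade-off
quadrant of the cost sign, so a costlier strategy with zero benefit is
never labelled dominant. Negative ICERs are always reported together
with their quadrant flag, since a bare negative ratio is ambiguous.

## Probabilistic sensitivity analysis

Per draw, sampled independently (no correlation structure is
available): annual births ~ Triangular(611,337; 648,107; 671,255) with
the base rate as mode; the four training rates and the litigation cost
~ Triangular(±20%); baseline probability and utilities ~ Beta with
method-of-moments shapes from (mean, sd), where sd is half the stated
range — except the population-norm utility, whose stated upper bound
is truncated at 1.00, so its sd is mean − min = 0.24. Infeasible beta
moments (variance ≥ mean(1−mean)) raise a validation error naming the
parameter. The decline schedule rescales proportionally to the sampled
baseline (preserving the piecewise-linear shape), and coverage keeps
its base-case proportions of the sampled birth rate.

One `SeedSequence` per run spawns one child stream per draw, so runs
are bit-reproducible from the seed and any single draw can be replayed
in isolation. Failed draws are recorded with their error message, not
dropped. Summaries are means with 2.5/97.5 **percentile** intervals
(the published intervals are asymmetric); ICER intervals are
percentiles of per-draw ratios, not ratios of percentile bounds. A
degenerate PSA with every distribution fixed reproduces the
deterministic base case bit-exactly.

Known limitation: with the stated mean ± sd utility ranges, about 16%
of independent draws put the affected-adult utility above the
population norm, making the adult QALY gain negative in those draws.
Published figures showing *every* adult-QALY draw as dominant imply a
much tighter utility spread than the stated ranges; we report what the
stated distributions produce.

## Synthetic inputs and the simulation oracle

The generator produces random but structurally valid inputs that
emulate the real input table: a handful of integer-sized coverage
cohorts summing to a drawn fraction of annual births, a two-segment
non-increasing decline schedule reaching zero between years 6 and 15,
and cost/utility scalars inside their validity domains. Defaults use
desk-scale birth rates (2,000–10,000/yr, roughly the national rate
scaled down by ~100) so stochastic checks run in seconds; the
deterministic engine is exactly linear in the birth rate, so
scaled-down comparisons lose no generality. What it does not emulate:
unit-level attendance records, demographic trends, or any correlation
between parameters — passing property tests therefore validates the
model's arithmetic and invariants, not the realism of any particular
national estimate.

The Bernoulli oracle simulates each birth as an independent trial at
its cohort-year probability (binomial sampling per cohort-year) and
agrees with the deterministic engine within 3 standard errors on
cumulative totals across ≥ 20 random configurations in the test suite.

## Problem sizes

The test suite uses 30–40 year horizons, PSAs of up to 1,000 draws,
oracle runs of 250–300 replicates at desk-scale birth rates, and 10⁵
draws for sampler-moment checks; the analysis scripts use the full
base case with 1,000-draw PSAs. These sizes match the study conditions
while keeping any run well under a minute.
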