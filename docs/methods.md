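# Methods

## Model

The unit of analysis is one specialty's salary ladder: starting
salaries S(rank, percentile) in constant 2025 USD for three academic
ranks (assistant < associate < full professor) and three survey
percentiles (25/50/75), plus a full-time career length T in whole years.
A promotion trajectory assigns a rank to each career year; a career plan
assigns an effort fraction to each year and may shorten the career. The
year-t salary is

    salary_t = S_{rank(t)} · (1 + g)^(t−1) · effort_t ,

i.e. the *entire rank ladder* inflates at wage growth g from year 1, so
a promotion in year k jumps to the new rank's ladder at its year-k
level. This "current starting salary for the current rank" convention
implies that promotion gains compound: earlier access to a higher
ladder is worth more than the one-year salary difference. Lifetime
earnings are the discounted sum

    NPV = Σ_t salary_t / (1 + r)^(t−1)            (beginning-of-year)

with the end-of-year convention (divide by one extra 1 + r) available by
flag. Beginning-of-year is the default because the year-1 salary is
"today's" starting salary and should enter at face value in constant
dollars; the two conventions differ by the exact factor (1 + r), which
is asserted as an identity in the tests.

Assumptions worth stating explicitly: promotions happen at year
boundaries (careers are modelled in whole years); part-time effort
scales salary multiplicatively and does not slow the promotion clock or
the growth base; no taxes, benefits, retirement accounts or training
opportunity costs; a trajectory whose promotion years exceed T simply
never reaches the later ranks (no error) — this is what "remainder"
means.

## Parameters

| parameter | default | meaning |
|---|---|---|
| g (wage growth) | 0.03 / yr | multiplicative annual raise applied to all ladders |
| r (discount rate) | 0.04 / yr | annual devaluation of future earnings |
| T (career length) | 35 yr (38 general peds/EM, 37 sports med) | full-time earning years |
| part-time window | final 10 yr at effort 0.5 | late-career part-time variant |
| early retirement | T − 10 yr | shortened-career variant |
| trajectories | 5+5, 7+7, 10+remainder, never | early / baseline / stalled / none |
| growth sweep | 0–5% step 1%, r fixed 4% | one-way sensitivity |
| discount sweep | 1–5% step 1%, g fixed 3% | one-way sensitivity |
| MC growth draw | TruncNormal(3%, 2%) on [1%, 5%] | per-iteration g |
| MC discount draw | TruncNormal(4%, 2%) on [2%, 6%] | per-iteration r |
| MC iterations | 10 000 | draws per analysis |
| break-even cap | 40 extra years | beyond this, "unreachable" is raised |

Career lengths follow the usual educational timeline (college + medical
school + residency + optional fellowship, retirement at 67), which is
why a 3-year-fellowship subspecialty earns for 35 years and general
pediatrics for 38.

## Numerical choices

* Three independent NPV routes are maintained: a vectorised kernel
  (`npv_draws`, used by both the deterministic base case and Monte
  Carlo), a stream-then-discount path (`salary_stream` + `npv`), and a
  piecewise-geometric closed form (one geometric series per maximal
  constant-rank, constant-effort span, with the x = (1+g)/(1+r) = 1
  degenerate case handled exactly). Tests require 1e-9 relative
  agreement on randomized inputs; observed agreement is ~1e-14.
* The deterministic scenario NPV is the length-1 call of the same
  kernel the Monte Carlo uses, so a degenerate (sd = 0) simulation
  equals the base case bit-for-bit rather than approximately.
* Monte Carlo draws one (g, r) pair per iteration, constant over the
  career, shared across trajectories (common random numbers). CRN makes
  the per-draw scenario ordering exact and shrinks the variance of
  scenario deltas; marginal NPV distributions are unaffected. Growth
  and discount draws are independent of each other. Sampling is
  inverse-CDF through `scipy.stats.truncnorm.ppf` (no rejection loop),
  seeded via `numpy.random.default_rng`; the seed is recorded in the
  result and in the report manifest.
* The break-even solver accumulates one discounted extension year at a
  time (extension years continue the deficit trajectory's final rank at
  full effort; the reference NPV is held at its original T). Every
  extension term is positive, so the extended NPV is strictly
  increasing and the first crossing is the minimum; the test suite
  checks the solver against an exhaustive from-scratch scan. Under
  heavy discounting the extended NPV is effectively capped, so
  "unreachable within max_extra" is an explicit error carrying the
  residual gap, not a sentinel. A fractional refinement linearly
  pro-rates the final year's discounted salary and is reported
  alongside the integer answer.
* Quartiles in box statistics use linear interpolation between closest
  ranks (numpy's `linear` method); whiskers are min/max. Salaries are
  carried to the cent with no internal rounding; display rounding
  happens only at the reporting layer. The report bundle is written to
  a temporary directory and moved into place, so a failed run leaves no
  partial output.

## Synthetic data

The generator emulates the *structure* of an academic-pediatrics
compensation survey, not its values: n specialties (default 29), an
assistant-professor 50th-percentile salary drawn uniformly on
$140k–$260k, two per-specialty rank-uplift factors on [1.08, 1.30], and
two percentile-spread factors on [1.06, 1.22]; the career-length mix is
two 38-year specialties, one 37-year, and the rest 35. The salary range
brackets published academic pediatric assistant-professor salaries; the
uplift and spread ranges produce full-professor and 75th-percentile
premia in the tens of percent, typical of rank/percentile gradients in
academic medicine. Monotonicity in rank and percentile is enforced by
construction (all factors > 1) because the model's dominance results
are stated for rank-monotone ladders; the CSV *validator*, by contrast,
only warns on inversions, since real survey data may contain them.

What passing tests on synthetic data do and do not show: they verify
the model's mathematics and its structural predictions (scenario
dominance, sweep monotonicity, crossover regimes, break-even
behaviour) on any rank-monotone schedule; they say nothing about the
dollar magnitudes of any real survey, and no synthetic default is
presented as a survey value. Dataset-dependent published figures are
therefore not reproduction targets. Real data with salary inversions
may violate per-year scenario dominance; the validator surfaces this
before analysis.

The frozen two-specialty worked fixture ("alpha": assistant/associate/
full = 100k/120k/150k at the 50th percentile, T = 35; "beta" = 1.5×
alpha, T = 38; percentile spread ±10%) exists so that examples and
brute-force oracles use round numbers.

## Design choices

* The promotion-vs-percentile crossover (promoted-at-25th out-earning
  never-promoted-at-75th) is exposed as a per-specialty comparison
  table rather than asserted universally: it holds when the rank uplift
  is large relative to the percentile spread, and the tests assert
  exactly that implication in both directions.
* Schedule-level Monte Carlo pooling is the per-draw mean across
  specialties, labelled `specialty_mean` in the output — an explicit
  aggregation choice, kept separate from per-specialty results.
* `career_years` is a per-specialty CSV column defaulting to 35;
  non-default lengths must be stated explicitly because free-text
  specialty names cannot be mapped to fellowship lengths reliably.
* Whether part-time status changes promotion timelines is unknown; the
  model keeps them unchanged and notes the assumption here.
* Problem sizes in the test suite (e.g. 1-specialty schedules inside
  the 500-schedule dominance scan, 2 000-draw MC in unit tests and
  10 000-draw MC in the end-to-end checks) are chosen so the whole
  suite completes in seconds while still exercising every code path at
  the documented defaults.

## Limitations

No mid-career specialty switches, no part-time periods other than the
final-10-year variant, no salary-level uncertainty in the Monte Carlo
(only g and r vary), no correlation between growth and discount draws,
and no modelling of taxes or benefits. Break-even answers are
data-dependent: on synthetic schedules with default uplifts the median
no-promotion-vs-baseline extension is on the order of a decade, but the
number for any real schedule must be computed from that schedule.
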