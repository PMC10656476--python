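# Methods

## Model structure

The projection is a deterministic annual recursion on population counts
indexed by (city, sex, single year of age 0–99 plus an open "100+"
interval).  Counts are real numbers throughout; nothing is rounded during
a run, because rounding each of ~90 annual steps accumulates bias.  The
open interval is absorbing: survivors of age 99 and surviving centenarians
pool there — any other convention silently loses people.

Each step composes, in order:

1. **Year rates.**  The baseline age-specific fertility schedule of every
   city is multiplied by one national factor so that the female-population-
   weighted national TFR equals the scenario's TFR path value (weights:
   baseline women aged 15–49, the exposed population; city-to-city
   fertility differences and schedule shapes are preserved).  The baseline
   mortality schedule of each city and sex is scaled (see "mortality
   inversion") to hit that year's life-expectancy target.  Internal
   migration rates come from the scenario rules below.
2. **Migration balancing** (per sex and single age; see below).
3. **Births** from previous-year women and the year's ASFR, split by the
   year's sex ratio at birth.  Newborns are *not* multiplied by the
   international migration factor; the recursion applies that factor only
   to the survival-plus-migration term of existing cohorts.
4. **Cohort advance**: survival, balanced net internal flow, international
   factor, ageing by one year.  A cohort driven below zero by out-migration
   is clamped at zero and the shortfall logged in the run's vitals — net
   rates applied to shrinking cohorts can otherwise produce negative
   people, and the log preserves auditability of the (tiny) mass imbalance.

The per-year bookkeeping identity
`total(t+1) = total(t) + births − deaths + net_international`
holds to floating-point accuracy whenever no clamping fires, and is
asserted in the test suite.  With all rates zero the system is a pure
shift and conserves mass exactly; with constant rates and no migration it
is exactly a Leslie-matrix iteration, which the tests exploit as an
independent oracle.

## Scenario parameter paths

* **Fertility (5 variants).**  All variants share the observed national
  history — 1.50 (2010, 2013), 1.88 (2017), 1.30 (2020), interpolated
  linearly — and diverge from 2021: linear to the variant's 2050 target
  (0.7 / 1.3 / 1.5 / 1.8 / 1.8) and on to its 2100 target
  (0.9 / 1.3 / 1.8 / 1.8 / 2.1), constant after 2100.
* **Sex ratio at birth.**  Linear from the baseline value (default 1.18;
  a knob of the synthetic world, not a published constant) to 1.07 at
  2050, constant thereafter.  Male share of births is SRB/(1+SRB).
* **International migration.**  A single national net rate of −0.3015‰
  per year applied to every cohort, constant through 2050 and declining
  linearly to exactly zero at 2100.  The published description of the
  decline's timing is internally contradictory; this package fixes the two
  unambiguous endpoints (the rate itself, and zero at 2100) and starts the
  decay at mid-century.
* **Mortality.**  Each city's life expectancy target at year *t* is
  `e0_city(2010) + (t−2010)/10 × e0_city(2010)/e0_national(2010)`: one
  year per decade, weighted by the city's initial ratio to the national
  level (cities starting below the national LE gain slightly less than a
  full year per decade, so the national average growth is a little under
  1 y/decade).  The national baseline e0 is the population-weighted mean
  of city values, per sex.
* **Internal migration.**  The 2010 net rate of each province (city) is
  carried to a 2020 value by a region (tier) multiplier — provinces:
  ±50% / ±25% / unchanged across the three scenarios, applied as an
  amplification of magnitude on both the gaining east and the losing
  middle-west; cities: tier-1 +100%, new-tier-1 +75%, tier-2 +50%,
  tier-3 −75% in the high-migration scenario, half-strength in the medium
  one, unchanged in the stable one.  Rates interpolate linearly from the
  2010 value to the 2020 multiple, then linearly to zero at 2035, and stay
  zero.  "Decrease 75%/25%" for tier-3 cities is read as shrinking the
  rate toward zero (reduced attractiveness), not deepening losses; the
  multiplier table is an argument, so the other reading is one dict away.
* **Policy overlays** (applied after the above, city level only): the
  settlement-reform factors scale the migration rate of cities below 3 M
  residents by 0.5 before 2020 and 0.1 from 2020, and of 3–5 M cities by
  0.5 / 0.25; the size class is evaluated from the *previous year-end*
  total, re-checked annually, because the policy keys on a population size
  that evolves.  A city at or above its population ceiling (e.g. 23 M for
  a Beijing-like megacity) gets migration rate 0 outright for that year;
  the check repeats annually, so migration resumes if the city later falls
  below its cap.  Order of application: scenario multiplier, temporal
  interpolation, size factor, ceiling override — the ceiling is stated as
  an absolute rule, so it comes last.

## Migration balancing

Modelling *net rates* at two levels over-determines the system, so two
constraints are enforced separately for every (sex, single age) cell:

* **National closure.**  Let S⁺ be the sum of positive provincial nets and
  S⁻ the magnitude of negative ones.  The larger side is scaled by
  min(S⁺,S⁻)/max(S⁺,S⁻); the smaller side is untouched.  This is the
  minimal perturbation consistent with "cut back the excess": factors lie
  in [0,1], no flow changes sign or grows, and the operation is
  idempotent.  The floating-point residual is assigned to the largest-
  magnitude entry so the constraint holds exactly.
* **Provincial consistency.**  Within a province, if the raw city sum C
  shares the sign of the adjusted provincial target T, city flows are
  rescaled by T/C.  If C = 0 or the signs disagree, multiplicative scaling
  is undefined or explosive, so the discrepancy T − C is distributed
  additively across the province's cities in proportion to their previous-
  year population of that cell (a province with zero population in a cell
  but a nonzero target is an error).  This fallback is isolated in one
  function.

## Mortality inversion

Life expectancy is computed from a standard period life table on
single-year death probabilities: a_x = ½ for closed ages, and open-
interval person-years l₁₀₀/m₁₀₀ with the central rate m derived from the
open death probability.  To hit a life-expectancy target, the whole
schedule is scaled uniformly, q′ = min(1, k·q), and k is solved by
bisection (scalar API: Brent; engine: a vectorised 64-step bisection over
all cities × sexes at once) to an e0 tolerance of 0.01 years.  Uniform
scaling is the simplest monotone one-parameter family; a Brass-logit
relational model is a documented alternative if age-pattern change
matters.  Because the mortality rule is scenario-independent, the per-year
schedules are computed once and shared across the 15-scenario grid.

## Synthetic baseline

The generator emulates the *structure* of a census baseline, not any real
country's numbers: no real city names, sizes or microdata.

* Geography: configurable provinces × cities; east provinces listed first
  (`round(east_fraction · n)`, at least one per region when n ≥ 2); tiers
  drawn from `tier_mix`; tier-1 cities get a ceiling of 3× the mean city
  size to exercise the cap logic.
* Mortality: Gompertz–Makeham hazard (background 1.5·10⁻⁴, slope 0.095,
  infant excess 3·10⁻³) with the level solved per city and sex so e0 lands
  within a ±0.3 y jitter of the configured target (defaults 72.4 M /
  77.4 F years).
* Fertility: gamma-shaped unimodal ASFR over ages 15–49 with a per-city
  peak age in 25–29, scaled so each city's TFR is within ±0.8% of the
  configured level (default 1.5).
* Pyramid: the Lotka stable-age distribution implied by the generated
  mortality and the fertility *shape*, anchored at replacement level
  (TFR 2.1) rather than the current sub-replacement level — a census
  pyramid reflects decades of past near-replacement fertility, and a
  stable pyramid at TFR 1.5 would be implausibly old (crude death rate
  ≈2.8%).  City sizes are lognormal (σ = 0.6) around the mean; cellwise
  lognormal noise (σ = 0.02) breaks exact stability.
* Migration: a Gaussian young-adult age profile (peak 25, σ 8 years);
  provincial scalars positive in the east and negative in the middle-west,
  with the gaining side rescaled so the profile-weighted national net flow
  is zero at baseline; city scalars vary ±30% around their province's.
* Randomness: one seed, split into named substreams (geography, mortality,
  fertility, pyramid, migration) via `SeedSequence`, so output is
  bit-identical across runs and insensitive to generation order.

What passing tests on this world do **not** show: calibration to any real
census, behaviour under administrative-boundary changes, education or
urbanization dimensions, or the realism of any particular city's path —
only the correctness and internal consistency of the projection machinery.

The pseudo-census used by the validation tests is the projection itself
run to a truth year with each city's counts multiplied by an independent
lognormal factor; with sd 0.05 the expected mean city APE is
E|1−f|/f ≈ 4%, which the error report recovers.

## Problem sizes and numerical choices

The default synthetic system is 5 provinces × 4 cities (50 M people); the
full 15-scenario 2010–2100 grid on it runs in a few seconds, and the
migration-balance checks use instances up to 10 × 10.  Balancing residuals
are driven to exact zero per cell (largest-entry absorption); oracle
comparisons use relative tolerance 10⁻⁹; the mortality inversion tolerance
is 0.01 y.  Output CSVs use fixed row ordering and shortest round-trip
float representation, so identical runs produce byte-identical files *and*
read-back reproduces in-memory values exactly (a fixed 6-significant-digit
format was considered and rejected for breaking exact read-back).

## Known limitations

* Net migration only — no origin–destination structure, so the model
  cannot say *where* a city's migrants come from.
* The additive fallback in city reconciliation is a modelling choice with
  no published counterpart; it only activates on sign mismatches, which
  are rare under consistent rate signs.
* Mortality change is a uniform proportional scaling of q; age-pattern
  shifts (e.g. faster old-age improvement) are out of scope.
* The TFR→ASFR allocation is a single national factor; city-specific
  fertility convergence is not modelled.
* End year is capped at 2100; paths are constant beyond their last anchor.
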