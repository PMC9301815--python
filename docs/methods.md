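# Methods

This note records the model's assumptions, the conventions chosen where the
design was genuinely open, and what the synthetic components do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort structure and mortality

The model is a deterministic two-state (alive/dead) cohort simulation. The
horizon runs from entry (mean age 58.1) to attained age 100; any cohort mass
still alive at the cap accrues nothing further (at the default inputs this
residual is well under 1% of the cohort). A year is 365 days throughout; leap
years are ignored.

Three mortality regimes partition the horizon:

1. **Trial window, days 1–28, daily cycles.** The cumulative 28-day risk in
   the control arm is taken from exact counts (548/5981). The within-window
   daily distribution of deaths is not recoverable from the published
   summaries, so the package ships two shapes — a geometric decay with
   per-day ratio 0.9 (default, emulating the observed front-loading of
   bleeding deaths) and a uniform alternative — normalised so the
   unconditional daily death fractions sum to the cumulative risk. Lifetime
   results are driven by the cumulative risk, not the shape: switching
   geometric→uniform moves discounted life years by under 0.1% (asserted in
   the test suite). The treatment effect is applied on the cumulative-risk
   scale — TXA-arm risk = RR × control risk with the daily shape preserved —
   because the trial's RR is a 28-day risk ratio; applying it per-day instead
   would change results negligibly at these magnitudes, but the convention is
   fixed here.
2. **Days 29–365, daily cycles.** General-population annual death
   probabilities at the floored attained age, inflated by the first-year SMR
   (5.21) and converted to daily probabilities by
   `1 − (1 − q)^(1/365)`.
3. **Years 2+, annual cycles.** Life-table mortality inflated by the
   long-term SMR (1.74), which applies for the rest of the horizon (the two
   SMRs are distinct rows of the input table; the year-one SMR governs only
   year one).

SMRs act on the hazard scale, `q' = 1 − (1 − q)^SMR`. Multiplying
probabilities directly would exceed 1 at old ages with SMR 5.21; on the
hazard scale the result is always a probability. At the default inputs the
two conventions differ by well under 1% of discounted life years.

## Life table

No official national life table can be redistributed here, so the vendored
table (`uk_life_table_synthetic.csv`) is **synthetic**: annual death
probabilities constructed by monotone (PCHIP) interpolation of the log
hazard through anchor values typical of recent UK all-persons period tables.
Its life expectancy is 80.6 years at birth and 25.4 at age 58, matching
published UK figures to within a few months. A fully parametric
Gompertz–Makeham generator (hazard `λ + a·e^{bx}`, defaults calibrated to
the same anchors) is available as an alternative source, and any
`age,q_annual` CSV can be supplied. The table is sex-aggregated; a cohort
with the trial's majority-male mix would carry slightly heavier mortality,
which is one reason lifetime totals can differ by a few percent across
plausible tables. Incremental results are much less sensitive, since both
arms share the life table.

## Accrual, discounting and the spreadsheet convention

Within each cycle, survivors accrue `cycle_length/365` life years weighted
by the survivor utility at the floored attained age (0.735, minus 0.02 from
age 65 and 0.07 from 75); QALY = LY × utility. Deaths accrue either nothing
(default) or half a cycle (`half_cycle_correction: true`). Discounting uses
the continuous-time exponent `(1 + r)^(−t/365)` with the factor taken at
each cycle's **end** by default (`discount_timing: start` is available); the
one-off entry cost is incurred at t = 0 undiscounted.

These two defaults — end-of-cycle deaths and end-of-cycle discounting — are
the classic discrete-time spreadsheet cohort convention, and the reference
results this package reproduces were produced by a spreadsheet model. The
choice matters only for the annual cycles (year one is daily): switching
both flags raises discounted life years by about 5%, and the package's
structural tests assert that the headline ICER is stable across all four
convention combinations. Both flags are exposed so either convention can be
reported.

## Costs

All costs are GBP 2021 as printed in the source tables; no further inflation
is applied. The one-off trial-period cost per arm is
`(LOS − ICU)·£338 + ICU·£1594` for the stay, `Σ p·tariff` over the five
procedure types, `Σ p·units·price` over the three transfusion products, and
the itemised TXA administration cost (drug £12, consumables £3.67, 21
minutes of Band 5 nurse time £14.35) in the TXA arm. The itemised components
sum to £30.02 against a printed total of £30.01 — a printed-rounding
discrepancy the tests document. Transfusion "mean units" are treated as
conditional on receiving the product, the only reading consistent with the
printed per-arm transfusion costs (probability × mean × unit price).

Post-discharge monitoring costs accrue among survivors: £4350 in year 1 —
pro-rated over days 29–365 only, since the costed inpatient episode covers
the trial window — then £1980 and £1938, and from year 4 a configurable
fraction (default 1/3) of the year-3 amount. Year boundaries are counted
from model entry. Storing the year-4+ value as a fraction makes the "full
monitoring from year 4" and "no monitoring beyond year 3" scenarios one-key
changes. The published "inpatient costs excluded in year 1" variant does not
state its year-1 amount; this package's version sets year-1 monitoring to
the year-2 level (£1980) and is reproduced qualitatively only.

## Probabilistic analysis

Each sampled parameter uses the distribution family its table row names,
fitted in closed form: log-normal for RR and SMRs with `μ = ln(point)`
(point = log-scale median, consistent with the CI symmetry of these
estimates on the log scale) and `σ = (ln hi − ln lo)/3.92`; Beta(k, n−k)
from exact counts for all probabilities; a method-of-moments beta for
utility from its mean and CI; gammas by moment matching for lengths of stay,
ICU days, transfusion units and the three monitoring costs, whose SE is
`psa_cost_se_fraction` × mean (0.5 base case, 0.2 as a variant). Parameters
without a distribution entry (unit costs, discount rates, utility
decrements, TXA administration) stay fixed. All draws are independent across
parameters and arms; no correlation structure is imposed. A drawn 28-day
risk rescales the daily curve proportionally, and the drawn RR multiplies
the drawn risk in the TXA arm. Drawn ICU days are capped at the drawn length
of stay.

Reproducibility: draw *i* of a run with master seed *s* is generated from
the substream seeded by `(s, i)`, so any draw can be regenerated in
isolation and results are independent of execution order. Degenerate
distributions return their point exactly, so a fully collapsed PSA
reproduces the deterministic result.

The default run is 10 000 draws (Monte Carlo standard error on a
probability near 36% is about 0.5 percentage points). A full 10 000-draw PSA
takes roughly 15 s on one CPU; the acceptance script's three PSAs complete
in about half a minute.

## Scenario analyses

The shipped deterministic scenarios are: base case; full/zero monitoring
from year 4; 0% and 6% discounting (costs and QALYs varied jointly — the
published wording is ambiguous about joint versus separate variation, and
separate flags exist); survivor utility 0.5; the qualitative year-1
monitoring variant; RR at its CI bounds (0.92, 1.16); and free TXA
administration. The pre-trial meta-analysis scenario replaces the control
risk with 71/850 and the RR with 0.60 (95% CI 0.42–0.87), in both the
deterministic and probabilistic analyses.

## Synthetic trial generator

`simulate_trial` emulates what the analysis assumes about the underlying
patient-level data: Bernoulli 28-day death at the arm's cumulative risk with
the configured daily curve as the death-day distribution; gamma lengths of
stay and ICU days (ICU redrawn until ≤ LOS; the truncation bias at the
default means is negligible); Bernoulli procedure and transfusion
indicators at the table proportions; and conditional-gamma transfusion
units, so the unconditional mean is probability × conditional mean. It does
**not** emulate within-patient correlation between resource items, arm
imbalance in baseline covariates, censoring, or any post-28-day individual
outcomes — so parameter-recovery tests demonstrate estimator correctness
under the model's own assumptions, not robustness to real-data violations
of them. `estimate_parameters` recovers the 28-day risk, the risk ratio
with a log-scale Wald 95% CI, and all resource-use summaries in the exact
shape of the parameter store, closing the data→inputs→results loop.

## Numerical choices and degenerate inputs

- Probability/rate conversions use `log1p`/`expm1` for accuracy at small
  risks; the daily-curve survival-product identity holds to 1e−12.
- Age lookups floor the attained age; start age 58.1 reads the age-58 row
  during year one. Life-table lookups clip at the last row.
- A zero cumulative risk yields an all-zero daily curve; beta fits with
  k ∈ {0, n}, zero SEs and degenerate CIs collapse to point masses rather
  than erroring.
- RR × risk ≥ 1 is rejected when building a schedule; PSA draws violating it
  would be redrawn from an extended substream (unreachable at the default
  inputs).
- Ties on the cost-effectiveness plane: zero incremental effect counts as
  east, zero incremental cost as north; zero net benefit splits evenly
  between strategies in the CEAC.

## Known limitations

- The life table is a synthetic UK-style stand-in, not official statistics;
  absolute lifetime totals carry a few percent of table uncertainty.
- Incremental quantities inherit the rounding of the printed inputs they are
  rebuilt from (notably the risk ratio, printed to two decimals), which
  bounds how closely absolute incrementals — and hence the INMB — can be
  reproduced from published summaries alone; ratio statistics (ICERs) are
  insensitive to this.
- No value-of-information analysis, no subgroup modelling, no competing-risk
  decomposition of mortality, and no microsimulation engine; the cohort
  proportions are the object of analysis.
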