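# txa-cea

A lifetime cost-effectiveness model of tranexamic acid (TXA) versus no-TXA,
in addition to usual care, for adults with acute gastrointestinal bleeding
(AGIB), from a UK NHS perspective with costs in 2021 GBP. It is written for
health economists and methodologists who want a tested, scriptable
re-implementation of this evaluation — the published original was a
spreadsheet model — with every input, convention and sensitivity analysis
exposed as configuration.

## The model

A two-state (*alive*/*dead*) Markov cohort model follows patients from a mean
entry age of 58.1 years to an age cap of 100:

- **Days 1–28** (daily cycles): deaths follow the trial's 28-day all-cause
  mortality. The control-arm cumulative risk is 548/5981 ≈ 0.092, spread over
  days by a front-loaded daily curve; the TXA arm's cumulative risk is
  RR × 0.092 with RR = 1.03 (95% CI 0.92–1.16). This window is the only place
  the treatment acts.
- **Days 29–365** (daily cycles): general-population mortality from a life
  table, inflated by a first-year standardised mortality ratio (SMR) of 5.21
  on the hazard scale, `q' = 1 − (1 − q)^SMR`, converted to daily
  probabilities.
- **Years 2+** (annual cycles): life-table mortality with the long-term
  SMR of 1.74.

Survivors accrue utility 0.735 (age-decremented by 0.02 from 65 and 0.07 from
75), a one-off trial-period cost (stay, procedures, transfusions, plus £30.01
TXA administration in the TXA arm), and post-discharge monitoring costs
(£4350/£1980/£1938 in years 1–3, one-third of the year-3 amount thereafter).
Costs and QALYs are discounted at 3.5% per annum. Results are reported as
incremental cost-effectiveness ratios (ICER = ΔC/ΔE) and incremental net
monetary benefit (INMB = λ·ΔE − ΔC) at λ = £20 000/QALY.

Uncertainty is handled the way the input tables describe it: log-normal
distributions for RR and the SMRs, betas from exact event counts for every
probability, method-of-moments betas for utility, gammas for lengths of stay,
transfusion units and monitoring costs (SE = 50% of the mean); a
10 000-draw Monte Carlo analysis yields the cost-effectiveness plane,
quadrant shares and acceptability curves. A deterministic scenario runner
covers the one-way sensitivity analyses, and a pre-trial scenario swaps in
meta-analytic evidence (control risk 71/850, RR 0.60, 95% CI 0.42–0.87).

Because the patient-level trial data are not openly downloadable, the package
also ships a synthetic trial generator (`txa_cea.trial`) that emulates
two-arm patient records with the assumed statistical structure, plus
estimators that recover the model inputs from such records. The bundled life
table is a synthetic UK-style all-persons table (see
`src/txa_cea/data/uk_life_table_synthetic.csv`); any `age,q_annual` CSV can
be substituted.

## Worked example

```sh
txa-cea base-case --out-dir out/
```

prints

```
                               no-TXA           TXA
Total costs (GBP)              18,420        18,361
Life years                      12.25         12.21
QALYs                            8.74          8.72
Incremental costs (GBP)                      -58.86
Incremental LYs                              -0.037
Incremental QALYs                            -0.026
ICER (per LY)                                 1,591
ICER (per QALY)                               2,228
INMB at 20,000/QALY                            -469
Quadrant                                         SW
```

TXA saves £59 per person (slightly cheaper hospital episode, fewer survivors
to incur monitoring costs) but loses 0.026 QALYs, because the mortality risk
ratio sits just above 1. The SW quadrant reading: £2,228 is saved per QALY
lost. Valuing a QALY at £20 000, the health forgone is worth more than the
saving — the INMB of −£469 means TXA is **not** cost-effective at the point
estimates. Full-precision CSVs (per-cycle traces, cost components) and a run
manifest land in `out/`.

The other subcommands follow the same pattern: `txa-cea dsa` (scenario
table), `txa-cea psa --n-draws 10000 --plot` (draws, CEAC, quadrants,
figures), `txa-cea scenario-meta` (pre-trial evidence scenario),
`txa-cea simulate-trial` and `txa-cea estimate` (synthetic records and
re-estimation). Library use mirrors the CLI:

```python
from txa_cea import default_parameters, load_life_table, run_base_case, run_psa

params = default_parameters()
lt = load_life_table(params.life_table)
print(run_base_case(params, lt).icer_qaly)   # 2228 (SW)
print(run_psa(params, lt, n_draws=10_000, seed=2021).p_cost_effective(20_000))
```

## Configuration

All inputs live in one YAML file (see
`src/txa_cea/data/default_config.yaml`, which is the complete base case).
Pass `--config my.yaml --use-defaults` to override selected keys, e.g. the
discount rates, the daily death-curve shape, the half-cycle and
discount-timing conventions, or a different life-table source. The documented
schema and `ParameterSet.to_json()` provide provenance logging for every run.
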