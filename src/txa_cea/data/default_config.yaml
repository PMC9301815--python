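# Default parameterisation: tranexamic acid (TXA) vs no-TXA for acute
# gastrointestinal bleeding, UK NHS perspective, GBP 2021.
#
# Schema notes
#   {value, ci: [lo, hi]}   point estimate with 95% CI
#   {mean, se}              mean with standard error (gamma-distributed in PSA)
#   {events, n}             count numerator/denominator (beta-distributed in PSA)
# Counts are stored rather than proportions so probabilistic sampling can use
# the exact trial numerators/denominators.

model:
  start_age: 58.1            # mean age at model entry, years
  horizon_age: 100.0         # absorption forced at this attained age
  discount_rate_costs: 0.035 # per annum
  discount_rate_qalys: 0.035
  wtp_threshold: 20000       # GBP per QALY
  half_cycle_correction: false  # true: deaths accrue half a cycle
  discount_timing: end       # end | start of cycle
  trial_curve:
    shape: geometric         # geometric | uniform daily death distribution
    ratio: 0.9               # per-day decay of the geometric shape

life_table:
  source: packaged           # packaged | file | gompertz_makeham
  path: null                 # used when source == file
  gompertz_makeham:          # used when source == gompertz_makeham
    makeham: 2.0e-4
    a: 1.25e-5
    b: 0.104

mortality:
  smr_year1: {value: 5.21, ci: [4.25, 6.38]}      # excess-mortality hazard multiplier, year 1
  smr_year2plus: {value: 1.74, ci: [1.42, 2.13]}  # years 2+
  rr_mortality: {value: 1.03, ci: [0.92, 1.16]}   # TXA vs no-TXA 28-day all-cause risk ratio
  risk28: {events: 548, n: 5981}                  # 28-day deaths in the no-TXA arm

utilities:
  survivor: {value: 0.735, ci: [0.70, 0.77]}
  decrements:                # absolute utility decrement from the given age
    - {min_age: 65, decrement: 0.02}
    - {min_age: 75, decrement: 0.07}

costs:
  txa_admin:                 # itemised one-off administration cost, TXA arm only
    drug: 12.00
    needle: 0.05
    syringe: 0.07
    infusion_bag: 0.59
    isotonic_solution: 2.96
    nurse_time: 14.35        # Band 5 nurse, 21 minutes
  unit:
    bed_day: 338             # non-ICU inpatient day
    icu_day: 1594
    procedures:
      endoscopy_diagnostic: 665
      endoscopy_therapeutic: 777
      surgery: 1377
      radiology_diagnostic: 4986
      radiology_therapeutic: 4986
    transfusions:            # per unit transfused
      blood: 132
      ffp: 31
      platelets: 192
  post_discharge:            # annual monitoring cost among survivors
    year1: 4350              # accrued over days 29-365 pro rata
    year2: 1980
    year3: 1938
    year4_plus_fraction: 0.3333333333333333  # fraction of year-3 cost from year 4 on

resource_use:
  txa:
    total_los_days: {mean: 5.83, se: 1.46}
    icu_days: {mean: 0.4, se: 0.46}
    procedures:
      endoscopy_diagnostic: {events: 4781, n: 5953}
      endoscopy_therapeutic: {events: 2542, n: 5953}
      surgery: {events: 146, n: 5953}
      radiology_diagnostic: {events: 1704, n: 5953}
      radiology_therapeutic: {events: 74, n: 5953}
    transfusions:            # mean units are conditional on receiving that product
      blood: {events: 3984, n: 5951, units: {mean: 2.80, se: 0.61}}
      ffp: {events: 910, n: 5951, units: {mean: 0.90, se: 0.61}}
      platelets: {events: 219, n: 5951, units: {mean: 0.20, se: 0.23}}
  no_txa:
    total_los_days: {mean: 5.80, se: 1.47}
    icu_days: {mean: 0.4, se: 0.51}
    procedures:
      endoscopy_diagnostic: {events: 4729, n: 5978}
      endoscopy_therapeutic: {events: 2658, n: 5978}
      surgery: {events: 158, n: 5978}
      radiology_diagnostic: {events: 1744, n: 5978}
      radiology_therapeutic: {events: 89, n: 5978}
    transfusions:
      blood: {events: 4018, n: 5978, units: {mean: 2.90, se: 0.69}}
      ffp: {events: 993, n: 5978, units: {mean: 1.0, se: 0.66}}
      platelets: {events: 255, n: 5978, units: {mean: 0.20, se: 0.26}}

psa:
  n_draws: 10000
  cost_se_fraction: 0.5      # SE of post-discharge costs as a fraction of the mean
  seed: 2021
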