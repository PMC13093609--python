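# Complete parameter configuration template (base-case point estimates).
# Any subset of keys may be overridden; add `use_defaults: true` to fill
# unlisted keys from the packaged defaults.  Costs in 2022/23 AUD;
# probabilities are annual.  `options` holds the modelling-convention
# flags documented in docs/methods.md.
diabetes_cost: 3997.0
diabetes_cost_growth: 0.05
diabetes_fraction_surgery: 0.101
diabetes_fraction_uc: 1.0
discount_rate: 0.05
distributions:
  diabetes_cost:
    kind: gamma
    mean: 3997.0
    sd: 248.0
  disutility_age:
    kind: beta
    mean: 0.003
    sd: 0.002
  disutility_diabetes:
    kind: beta
    mean: 0.116
    sd: 0.034
  down_uc:
    kind: beta
    mean: 0.0557
    sd: 0.0047
  initial_age:
    kind: triangular
    max: 65.0
    mean: 52.4
    min: 28.1
    mode: 52.4
  management_cost_ob1:
    kind: gamma
    mean: 7574.0
    sd: 16008.0
  management_cost_ob2_ob3:
    kind: gamma
    mean: 8926.0
    sd: 18599.0
  management_cost_ow:
    kind: gamma
    mean: 6762.0
    sd: 15568.0
  surgery_cost_ob1_ob2:
    kind: gamma
    mean: 15734.0
    sd: 12886.0
  surgery_cost_ob3:
    kind: gamma
    mean: 18242.0
    sd: 21165.0
  surgical_mortality:
    kind: beta
    mean: 0.005
    sd: 0.01
  up_surgery:
    kind: beta
    mean: 0.018
    sd: 0.006
  up_uc:
    kind: beta
    mean: 0.0603
    sd: 0.0047
  utility_ob1:
    kind: beta
    mean: 0.73
    sd: 0.229
  utility_ob2:
    kind: beta
    mean: 0.599
    sd: 0.252
  utility_ob3:
    kind: beta
    mean: 0.55
    sd: 0.275
  utility_ow:
    kind: beta
    mean: 0.782
    sd: 0.212
disutility_age: 0.003
disutility_diabetes: 0.116
down_surgery: 0.0
down_uc: 0.0557
horizon_cycles: 40
inflator_ob2: 0.05
inflator_ob3: 0.1
initial_age: 52.4
initial_distribution:
  OB1: 0.005
  OB2: 0.2
  OB3: 0.795
  OW: 0.0
management_cost:
  OB1: 7574.0
  OB2: 8926.0
  OB3: 8926.0
  OW: 6762.0
options:
  class_inflator_mode: differential
  compound_diabetes_cost: true
  half_cycle_correction: false
  horizon_mode: cycles
  monotone_utilities: false
  surgery_cost_replaces_management: true
  sw_below_wtp: always
  year1_timing: entry
rr_diabetes_mortality: 1.54
sa_ranges:
  diabetes_fraction_surgery:
  - 0.05
  - 0.15
  discount_rate:
  - 0.03
  - 0.07
  horizon_cycles:
  - 25
  - 55
  inflator_ob2:
  - 0.0
  - 0.1
  inflator_ob3:
  - 0.0
  - 0.2
  initial_age:
  - 28.0
  - 65.0
  rr_diabetes_mortality:
  - 1.33
  - 1.78
surgery_cost:
  OB1: 15734.0
  OB2: 15734.0
  OB3: 18242.0
surgical_mortality: 0.005
up_surgery: 0.018
up_uc: 0.0603
utilities:
  OB1: 0.73
  OB2: 0.599
  OB3: 0.55
  OW: 0.782
wtp: 64000.0
year1_surgery_transitions:
  OB1:
    OB1: 0.0
    OW: 1.0
  OB2:
    OB1: 0.31
    OB2: 0.05
    OW: 0.64
  OB3:
    OB1: 0.23
    OB2: 0.19
    OB3: 0.24
    OW: 0.34
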