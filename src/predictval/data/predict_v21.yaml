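# PREDICT v2.1 coefficient set, transcribed from the publicly released
# model source (fractional-polynomial prognostic-index terms per ER
# stratum, parametric baseline log cumulative hazards, adjuvant
# treatment log hazard ratios).  The chemotherapy entry uses the
# second-generation-regimen effect, the common regimen class when a
# cohort records chemotherapy only as a yes/no flag.
version: "2.1"

mi:
  a: 0.0698252
  b: 34.23391957

pi_terms:
  positive:
    - covariate: age_years
      coefficient: 34.53642
      transform: {divisor: 10, power: -2}
      center: 0.0287449295
    - covariate: age_years
      coefficient: -34.20342
      transform: {divisor: 10, power: -2, with_log: true}
      center: 0.0510121013
    - covariate: size_mm
      coefficient: 0.7530729
      transform: {divisor: 100, power: 0}
      center: -1.545233938
    - covariate: nodes
      coefficient: 0.7060723
      transform: {shift: 1, divisor: 10, power: 0}
      center: -1.387566896
    - covariate: grade
      coefficient: 0.746655
      transform: {power: 1}
      center: 0.0
    - covariate: detection
      levels: {screening: -0.22763366, symptoms: 0.0, unknown: -0.04643726664}
    - covariate: her2
      levels: {positive: 0.2413, negative: -0.0762, unknown: 0.0}
    - covariate: ki67
      levels: {positive: 0.14904, negative: -0.11333, unknown: 0.0}
  negative:
    - covariate: age_years
      coefficient: 0.0089827
      transform: {power: 1}
      center: 56.3254902
    - covariate: size_mm
      coefficient: 2.093446
      transform: {divisor: 100, power: 0.5}
      center: 0.5090456276
    - covariate: nodes
      coefficient: 0.6260541
      transform: {shift: 1, divisor: 10, power: 0}
      center: -1.086916249
    - covariate: grade
      levels: {"1": 0.0, "2": 1.129091, "3": 1.129091}
    - covariate: her2
      levels: {positive: 0.2413, negative: -0.0762, unknown: 0.0}

baseline_breast:
  positive:
    kind: parametric
    intercept: 0.7424402
    terms:
      - {coef: -7.527762, power: -0.5}
      - {coef: -1.812513, power: -0.5, with_log: true}
    support: [0.25, 15.0]
  negative:
    kind: parametric
    intercept: -1.156036
    terms:
      - {coef: 0.4707332, power: -2}
      - {coef: -3.51355, power: -1}
    support: [0.3, 15.0]

baseline_other:
  kind: parametric
  intercept: -6.052919
  terms:
    - {coef: 1.079863, power: 0}
    - {coef: 0.3255321, power: 0.5}
  support: [0.25, 15.0]

treatments:
  hormone: -0.3857
  chemo: -0.248
  trastuzumab: -0.3567
  bisphosphonates: -0.198

ranges:
  age_years: [25, 85]
  size_mm: [1, 300]
  nodes: [0, 100]
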