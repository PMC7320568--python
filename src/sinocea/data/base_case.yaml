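# Base-case comparison: intensity-modulated proton therapy (IMPT) versus
# intensity-modulated photon radiotherapy (IMRT) for paranasal sinus and
# nasal cavity cancer, Chinese payer perspective, all amounts in US$.
# 47-year-old cohort cycled annually to the 77-year life-expectancy endpoint.
strategies:
  - name: IMPT
    p_eradicate: 0.9
    cost_radiotherapy: 50000
    cost_chemo: 5000
  - name: IMRT
    p_eradicate: 0.73
    cost_radiotherapy: 12000
    cost_chemo: 5000
disease:
  relapse_schedule:       # annual "no cancer" -> "alive with cancer"
    - {from_year: 1, to_year: 3, prob: 0.10}
    - {from_year: 4, to_year: 5, prob: 0.05}
    - {from_year: 6, to_year: 10, prob: 0.01}
    # years 11+ carry zero relapse risk
  p_cancer_death: 0.3     # annual "alive with cancer" -> death
  utilities:
    no_cancer: 0.94
    with_cancer: 0.47
    death: 0.0
    # first_year omitted: the first post-radiotherapy year uses the
    # with-cancer utility (treatment disutility), tracking any PSA draw
  costs:
    followup_per_year: 1000
    palliative_per_year: 5000
settings:
  start_age: 47
  horizon: auto           # endpoint age - start age = 30 cycles
  discount_rate: 0.03
  life_expectancy_endpoint: 77
wtp: [30828, 50000, 100000]   # 3x Chinese 2019 GDP per capita, plus alternates
psa:
  n_iterations: 50000
  distributions:
    - {path: strategy_a.c_radiotherapy, kind: normal, mean: 50000, ci90: [37258.3, 62775.4]}
    - {path: strategy_b.c_radiotherapy, kind: normal, mean: 12000, ci90: [10723.2, 13287.5]}
    - {path: c_chemo, kind: normal, mean: 5000, ci90: [3710.4, 6284.7]}
    - {path: disease.c_followup, kind: normal, mean: 1000, ci90: [872.1, 1127.8]}
    - {path: disease.c_palliative, kind: normal, mean: 5000, ci90: [3724.0, 6269.1]}
    - {path: disease.u_no_cancer, kind: beta, mean: 0.94, ci90: [0.822, 1.0]}
    - {path: disease.u_with_cancer, kind: beta, mean: 0.47, ci90: [0.343, 0.598]}
    - {path: strategy_a.p_eradicate, kind: beta, mean: 0.9, ci90: [0.833, 0.957]}
    - {path: strategy_b.p_eradicate, kind: beta, mean: 0.73, ci90: [0.665, 0.792]}
    - {path: disease.p_cancer_death, kind: beta, mean: 0.3, ci90: [0.237, 0.365]}
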