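settings:
  cycle_length_months: 2.0
  start_age_years: 50.0
  max_age_years: 100.0
  residual_alive_tol: 0.0001
  discount_rate_costs: 0.03
  discount_rate_outcomes: 0.03
  half_cycle_correction: false
  normalization_policy: proportional
  risk_ratio_mode: hazard
  discount_compounding: annual
  exchange_rate_idr_per_usd: 14250.0
  wtp_usd_per_qaly: 10800.0
  background_mortality_per_cycle: 0.0
scenario:
  data_source: secondary
  perspective: healthcare
transition_probabilities:
  chemo_secondary:
    progression_free_to_progression_free:
      value: 0.877
      alpha: 125.0
      beta: 15.0
    progression_free_to_progressive:
      value: 0.116
      alpha: null
      beta: null
    progression_free_to_death:
      value: 0.006
      alpha: null
      beta: null
    progressive_to_progressive:
      value: 0.963
      alpha: null
      beta: null
    progressive_to_death:
      value: 0.037
      alpha: 124.0
      beta: 33.0
  chemo_real_world:
    progression_free_to_progression_free:
      value: 0.95
      alpha: null
      beta: null
    progression_free_to_progressive:
      value: 0.043
      alpha: 124.0
      beta: 33.0
    progression_free_to_death:
      value: 0.006
      alpha: null
      beta: null
    progressive_to_progressive:
      value: 0.974
      alpha: null
      beta: null
    progressive_to_death:
      value: 0.026
      alpha: 3.0
      beta: 13.0
  chemo_bev_real_world:
    progression_free_to_progression_free:
      value: 0.955
      alpha: null
      beta: null
    progression_free_to_progressive:
      value: 0.038
      alpha: 35.0
      beta: 61.0
    progression_free_to_death:
      value: 0.006
      alpha: null
      beta: null
    progressive_to_progressive:
      value: 0.957
      alpha: null
      beta: null
    progressive_to_death:
      value: 0.043
      alpha: 7.0
      beta: 28.0
risk_ratios:
  progression_free_survival:
    value: 0.72
    se: 0.0306
  overall_survival:
    value: 0.84
    se: 0.0357
costs_idr:
  chemo:
    progression_free:
      direct_medical:
        mean: 14671335.0
        se: 2001108.0
      direct_nonmedical:
        mean: 1585498.0
        se: 1585498.0
      indirect:
        mean: 225150.0
        se: 225150.0
    progressive:
      direct_medical:
        mean: 11002640.0
        se: 3215142.0
      direct_nonmedical:
        mean: 1585498.0
        se: 1585498.0
      indirect:
        mean: 225150.0
        se: 225150.0
  chemo_bev:
    progression_free:
      direct_medical:
        mean: 16581540.0
        se: 1297381.0
      direct_nonmedical:
        mean: 1635927.0
        se: 1635927.0
      indirect:
        mean: 137468.0
        se: 137468.0
    progressive:
      direct_medical:
        mean: 13571535.0
        se: 3045121.0
      direct_nonmedical:
        mean: 1635927.0
        se: 1635927.0
      indirect:
        mean: 137468.0
        se: 137468.0
utilities:
  chemo:
    progression_free:
      mean: 0.864
      se: 0.07
    progressive:
      mean: 0.724
      se: 0.07
  chemo_bev:
    progression_free:
      mean: 0.793
      se: 0.107
    progressive:
      mean: 0.659
      se: 0.131
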