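# Canonical model parameters for the PD-first vs HD-first cost-utility model.
# All costs in 2021 USD (1 USD = 33.57 THB); probabilities and utilities per year.
# Each entry: point estimate (mean), 95% interval (low, high), PSA distribution.
settings:
  discount_rate: 0.03
  perspective: societal
  start_age: 55.7
  age_cap: 100
  wtp: 4766
  psa_iterations: 5000
  fx_rate: 33.57

transitions:
  PD:   # initial-modality stratum: cohort started on peritoneal dialysis
    p_switch: {mean: 0.039, low: 0.035, high: 0.044, dist: beta}
    p_pd_to_pd_cc: {mean: 0.162, low: 0.148, high: 0.177, dist: beta}
    p_hd_to_hd_cc: {mean: 0.301, low: 0.248, high: 0.366, dist: beta}
    p_acute:
      PD: {mean: 0.052, low: 0.050, high: 0.054, dist: beta}
      PD_CC: {mean: 0.106, low: 0.103, high: 0.111, dist: beta}
      HD: {mean: 0.154, low: 0.146, high: 0.163, dist: beta}
      HD_CC: {mean: 0.203, low: 0.164, high: 0.250, dist: beta}
  HD:   # initial-modality stratum: cohort started on hemodialysis
    p_switch: {mean: 0.0073, low: 0.0065, high: 0.0081, dist: beta}
    p_pd_to_pd_cc: {mean: 0.557, low: 0.445, high: 0.698, dist: beta}
    p_hd_to_hd_cc: {mean: 0.168, low: 0.162, high: 0.175, dist: beta}
    p_acute:
      PD: {mean: 0.036, low: 0.035, high: 0.036, dist: beta}
      PD_CC: {mean: 0.080, low: 0.079, high: 0.082, dist: beta}
      HD: {mean: 0.256, low: 0.243, high: 0.270, dist: beta}
      HD_CC: {mean: 0.138, low: 0.113, high: 0.168, dist: beta}

costs:
  setup:  # one-time on entering a modality; +/- 10% range, uniform for PSA
    PD: {mean: 208.52, low: 187.668, high: 229.372, dist: uniform}
    HD: {mean: 357.46, low: 321.714, high: 393.206, dist: uniform}
  annual_direct_medical:
    PD: {mean: 7955.20, low: 7031.28, high: 9079.12, dist: exponential}
    PD_CC: {mean: 9220.85, low: 7561.45, high: 11967.08, dist: exponential}
    HD: {mean: 9079.12, low: 7915.28, high: 10943.22, dist: exponential}
    HD_CC: {mean: 12120.91, low: 8800.51, high: 19493.12, dist: exponential}
  acute_addon: {mean: 251.06, low: 27.70, high: 685.43, dist: exponential}
  acute_chronic_addon: {mean: 487.55, low: 97.68, high: 1104.71, dist: exponential}
  annual_direct_nonmedical:
    PD: {mean: 98.90, low: 44.53, high: 152.22, dist: gamma}
    PD_CC: {mean: 215.22, low: 96.89, high: 331.55, dist: gamma}
    HD: {mean: 1519.58, low: 586.15, high: 2101.44, dist: gamma}
    HD_CC: {mean: 1546.07, low: 596.34, high: 2138.00, dist: gamma}
  annual_indirect:
    PD: {mean: 78.46, low: 0.0, high: 143.77, dist: gamma}
    PD_CC: {mean: 170.75, low: 0.0, high: 313.15, dist: gamma}
    HD: {mean: 1004.71, low: 0.0, high: 3157.69, dist: gamma}
    HD_CC: {mean: 1022.22, low: 0.0, high: 3212.64, dist: gamma}

utilities:
  PD: {mean: 0.731, low: 0.689, high: 0.772, dist: beta}
  PD_CC: {mean: 0.599, low: 0.506, high: 0.692, dist: beta}
  HD: {mean: 0.811, low: 0.786, high: 0.837, dist: beta}
  HD_CC: {mean: 0.639, low: 0.567, high: 0.712, dist: beta}
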