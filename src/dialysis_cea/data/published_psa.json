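{
  "iterations": 5000,
  "mean_cost_hd": 91458,
  "mean_cost_pd": 57282,
  "mean_cost_diff": 34176,
  "mean_qaly_hd": 4.28,
  "mean_qaly_pd": 3.19,
  "mean_qaly_diff": 1.10,
  "wtp": 4766,
  "ceac_crossover_wtp": 25320,
  "tornado_icer_low": 22000,
  "tornado_icer_high": 51000,
  "perspective": "societal",
  "age": 55.7
}
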