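{
  "PD": {
    "shape": 0.8939867272308403,
    "scale": 5.558341912767699,
    "coefficients": {
      "age": -0.030810814783276408,
      "age2": -9.839121869588426e-05
    },
    "chronic_hazard_multiplier": 1.000000001010657,
    "stratum": "PD",
    "age_center": 50.0,
    "diagnostics": {
      "targets": {
        "20.0": 9.85,
        "30.0": 8.42,
        "40.0": 6.71,
        "50.0": 5.4,
        "60.0": 4.32
      },
      "residuals": {
        "20.0": 0.04465123872466137,
        "30.0": -0.12435267461373911,
        "40.0": 0.08361713534237847,
        "50.0": 0.040582096748400076,
        "60.0": -0.046861028736092436
      },
      "rms": 0.07522234869612114,
      "converged": true,
      "discounted_targets": true
    }
  },
  "HD": {
    "shape": 1.0806179844414563,
    "scale": 27.683394826938873,
    "coefficients": {
      "age": -0.05515610385385257,
      "age2": -0.00046752651667886924
    },
    "chronic_hazard_multiplier": 9.999999999998112,
    "stratum": "HD",
    "age_center": 50.0,
    "diagnostics": {
      "targets": {
        "20.0": 11.84,
        "30.0": 10.37,
        "40.0": 8.36,
        "50.0": 6.8,
        "60.0": 5.49
      },
      "residuals": {
        "20.0": 0.04960486087506766,
        "30.0": -0.1475187169776433,
        "40.0": 0.11409594144591573,
        "50.0": 0.05028523717483502,
        "60.0": -0.06726484135481758
      },
      "rms": 0.0941206267465457,
      "converged": true,
      "discounted_targets": true
    }
  }
}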