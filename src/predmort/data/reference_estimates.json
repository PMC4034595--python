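{
  "description": "Published point estimates of the trait-mortality model from the original predation-trial analysis (posterior means, medians and equal-tailed 95% credible intervals). sigma_predator is the among-predator (interspecific) SD, sigma_obs the trial-level (intraspecific, overdispersion) SD.",
  "full": {
    "mean": {
      "intercept": -3.06,
      "log_mass": 1.05,
      "log_mass_sq": -0.19,
      "ambush": 2.25,
      "suctorial": 2.20,
      "pelagic": 0.27,
      "sigma_predator": 2.24,
      "sigma_obs": 0.29
    },
    "median": {
      "intercept": -3.02,
      "log_mass": 1.02,
      "log_mass_sq": -0.19,
      "ambush": 2.21,
      "suctorial": 2.14,
      "pelagic": 0.30,
      "sigma_predator": 2.04,
      "sigma_obs": 0.25
    },
    "ci95": {
      "intercept": [-6.29, -0.08],
      "log_mass": [0.02, 2.30],
      "log_mass_sq": [-0.81, 0.39],
      "ambush": [-2.26, 7.03],
      "suctorial": [-1.02, 5.81],
      "pelagic": [-4.45, 4.79],
      "sigma_predator": [1.13, 4.46],
      "sigma_obs": [0.08, 0.68]
    },
    "explained_variance_pct": {"mean": 64.1, "median": 64.3}
  },
  "reduced": {
    "mean": {
      "intercept": -3.35,
      "log_mass": 1.00,
      "ambush": 2.38,
      "suctorial": 2.15,
      "sigma_predator": 1.89,
      "sigma_obs": 0.28
    },
    "median": {
      "intercept": -3.32,
      "log_mass": 0.98,
      "ambush": 2.38,
      "suctorial": 2.11,
      "sigma_predator": 1.77,
      "sigma_obs": 0.25
    },
    "ci95": {
      "intercept": [-5.79, -1.08],
      "log_mass": [0.13, 1.96],
      "ambush": [-0.33, 5.09],
      "suctorial": [-0.29, 4.77],
      "sigma_predator": [1.04, 3.42],
      "sigma_obs": [0.08, 0.68]
    },
    "explained_variance_pct": {"mean": 63.2, "median": 63.3}
  }
}
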