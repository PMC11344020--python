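{
  "provenance": "Pooled EXSCEL+TECOS published coefficient tables (3-decimal printed precision); dynamic-model residual/random-effect SDs were not published and default to 0.",
  "dynamic": {
    "hdl": {
      "unit": "mmol/l",
      "phi0": 0.188, "phi1": 0.238, "phi2": 0.506, "phi3": 0.055,
      "phi4_white": 0.019, "phi4_black": 0.045, "phi4_asian": 0.015,
      "phi5": 0.001, "phi6": -0.001,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.014, "phi1": 0.018, "phi2": 0.021, "phi3": 0.003,
             "phi4_white": 0.005, "phi4_black": 0.008, "phi4_asian": 0.006,
             "phi5": 0.000, "phi6": 0.002},
      "r2": 0.60, "n_obs": 37792, "n_patients": 18499
    },
    "ldl": {
      "unit": "mmol/l",
      "phi0": 1.027, "phi1": 0.295, "phi2": 0.383, "phi3": 0.100,
      "phi4_white": -0.001, "phi4_black": 0.032, "phi4_asian": -0.037,
      "phi5": -0.004, "phi6": -0.037,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.044, "phi1": 0.011, "phi2": 0.012, "phi3": 0.009,
             "phi4_white": 0.019, "phi4_black": 0.027, "phi4_asian": 0.020,
             "phi5": 0.001, "phi6": 0.008},
      "r2": 0.51, "n_obs": 35554, "n_patients": 17523
    },
    "sbp": {
      "unit": "mmHg",
      "phi0": 56.461, "phi1": 0.271, "phi2": 0.291, "phi3": 0.356,
      "phi4_white": 0.365, "phi4_black": 0.780, "phi4_asian": -0.416,
      "phi5": 0.027, "phi6": 0.034,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.850, "phi1": 0.006, "phi2": 0.007, "phi3": 0.136,
             "phi4_white": 0.271, "phi4_black": 0.442, "phi4_asian": 0.307,
             "phi5": 0.008, "phi6": 0.122},
      "r2": 0.30, "n_obs": 54790, "n_patients": 24115
    },
    "hba1c": {
      "unit": "%",
      "phi0": 2.945, "phi1": 0.456, "phi2": 0.243, "phi3": 0.031,
      "phi4_white": -0.082, "phi4_black": 0.065, "phi4_asian": -0.091,
      "phi5": -0.012, "phi6": 0.083,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.064, "phi1": 0.009, "phi2": 0.009, "phi3": 0.010,
             "phi4_white": 0.021, "phi4_black": 0.035, "phi4_asian": 0.023,
             "phi5": 0.001, "phi6": 0.009},
      "r2": 0.50, "n_obs": 51453, "n_patients": 22741
    },
    "haemoglobin": {
      "unit": "g/dl",
      "phi0": 3.698, "phi1": 0.329, "phi2": 0.462, "phi3": -0.177,
      "phi4_white": -0.037, "phi4_black": -0.208, "phi4_asian": -0.081,
      "phi5": -0.010, "phi6": -0.096,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.149, "phi1": 0.016, "phi2": 0.017, "phi3": 0.018,
             "phi4_white": 0.037, "phi4_black": 0.049, "phi4_asian": 0.042,
             "phi5": 0.001, "phi6": 0.015},
      "r2": 0.65, "n_obs": 22657, "n_patients": 12116
    },
    "heart_rate": {
      "unit": "bpm",
      "phi0": 30.755, "phi1": 0.283, "phi2": 0.346, "phi3": 0.560,
      "phi4_white": 0.316, "phi4_black": 0.376, "phi4_asian": 1.389,
      "phi5": -0.059, "phi6": -0.186,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.563, "phi1": 0.007, "phi2": 0.007, "phi3": 0.085,
             "phi4_white": 0.155, "phi4_black": 0.261, "phi4_asian": 0.184,
             "phi5": 0.005, "phi6": 0.075},
      "r2": 0.40, "n_obs": 53928, "n_patients": 23867
    },
    "bmi": {
      "unit": "kg/m2",
      "phi0": 1.219, "phi1": 0.684, "phi2": 0.289, "phi3": 0.039,
      "phi4_white": 0.022, "phi4_black": -0.079, "phi4_asian": -0.078,
      "phi5": -0.008, "phi6": 0.000,
      "resid_sd": 0.0, "re_sd": 0.0,
      "se": {"phi0": 0.094, "phi1": 0.023, "phi2": 0.023, "phi3": 0.015,
             "phi4_white": 0.028, "phi4_black": 0.044, "phi4_asian": 0.030,
             "phi5": 0.001, "phi6": 0.013},
      "r2": 0.95, "n_obs": 53885, "n_patients": 23747
    }
  },
  "survival": {
    "AF": {
      "betas": {"constant": -11.269, "age_at_rand": 0.060, "female": -0.576,
                "eth_white": 1.073, "eth_black": 1.150,
                "lag:bmi": 0.058, "lag:hdl": -0.487},
      "ln_gamma": 0.191,
      "covariate_spec": ["age_at_rand", "female", "eth_white", "eth_black",
                         "lag:bmi", "lag:hdl"],
      "se": {"constant": 0.572, "age_at_rand": 0.006, "female": 0.124,
             "eth_white": 0.198, "eth_black": 0.303,
             "lag:bmi": 0.007, "lag:hdl": 0.176, "ln_gamma": 0.076},
      "n_obs": 46281, "n_events": 416
    },
    "ALB": {
      "betas": {"constant": -8.590, "age_at_rand": 0.011, "female": -0.298,
                "eth_white": 0.291, "lag:bmi": 0.028, "lag:sbp": 0.011,
                "lag:hba1c": 0.102},
      "ln_gamma": 0.204,
      "covariate_spec": ["age_at_rand", "female", "eth_white",
                         "lag:bmi", "lag:sbp", "lag:hba1c"],
      "se": {"constant": 0.614, "age_at_rand": 0.005, "female": 0.092,
             "eth_white": 0.104, "lag:bmi": 0.006, "lag:sbp": 0.003,
             "lag:hba1c": 0.034, "ln_gamma": 0.060},
      "n_obs": 34627, "n_events": 596
    },
    "PVD": {
      "betas": {"constant": -11.596, "age_at_rand": 0.030, "eth_white": 1.120,
                "smoker_baseline": 0.465, "lag:hba1c": 0.151},
      "ln_gamma": 0.443,
      "covariate_spec": ["age_at_rand", "eth_white", "smoker_baseline",
                         "lag:hba1c"],
      "se": {"constant": 0.803, "age_at_rand": 0.008, "eth_white": 0.216,
             "smoker_baseline": 0.124, "lag:hba1c": 0.054, "ln_gamma": 0.090},
      "n_obs": 52412, "n_events": 219
    },
    "EGFR_LT60": {
      "betas": {"constant": 0.706, "first:egfr": -0.037, "lag:egfr": -0.032},
      "ln_gamma": 0.078,
      "covariate_spec": ["first:egfr", "lag:egfr"],
      "se": {"constant": 0.299, "first:egfr": 0.002, "lag:egfr": 0.003,
             "ln_gamma": 0.060},
      "n_obs": 53765, "n_events": 755
    }
  },
  "tobit": {
    "below60": {
      "betas": {"constant": 36.058, "age_at_rand": -0.100, "first:egfr": 0.232,
                "lag:egfr": 0.459, "lag:sbp": -0.025, "ln_duration": -1.335},
      "sigma": 11.888,
      "lower_limit": 0.0, "upper_limit": 60.0,
      "se": {"constant": 1.611, "age_at_rand": 0.016, "first:egfr": 0.015,
             "lag:egfr": 0.016, "lag:sbp": 0.007, "ln_duration": 0.228},
      "n_obs": 37997
    },
    "atabove60": {
      "betas": {"constant": 36.317, "age_at_rand": -0.230, "first:egfr": 0.446,
                "lag:egfr": 0.303, "lag:sbp": -0.011, "ln_duration": -0.753},
      "sigma": 13.839,
      "lower_limit": 60.0, "upper_limit": null,
      "se": {"constant": 1.108, "age_at_rand": 0.011, "first:egfr": 0.010,
             "lag:egfr": 0.011, "lag:sbp": 0.005, "ln_duration": 0.164},
      "n_obs": 37997
    }
  }
}
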