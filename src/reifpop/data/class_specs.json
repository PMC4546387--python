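{
  "_comment": "Built-in per-class statistics of pyramidal-cell EIF/rEIF parameters: natural-scale (mu, sigma) marginals (log-normal unless family says normal), transformed-space covariance over (log C, log tau, E, V_T, log Delta_T), Spearman rank correlations (lower triangle, for validation only), sag fractions and the class-independent mono-exponential fallback for the post-spike E dynamics.",
  "eif_order": ["C", "tau", "E", "V_T", "Delta_T"],
  "mono_fallback": {
    "E_mono": {"family": "lognormal", "mu": 16.1, "sigma": 4.8, "units": "mV"},
    "tau_mono": {"family": "lognormal", "mu": 15.1, "sigma": 4.5, "units": "ms"}
  },
  "classes": {
    "L23": {
      "eif_marginals": {
        "C": {"family": "lognormal", "mu": 134.0, "sigma": 32.8, "units": "pF"},
        "tau": {"family": "lognormal", "mu": 14.6, "sigma": 2.53, "units": "ms"},
        "E": {"family": "normal", "mu": -79.3, "sigma": 4.27, "units": "mV"},
        "V_T": {"family": "normal", "mu": -49.5, "sigma": 3.81, "units": "mV"},
        "Delta_T": {"family": "lognormal", "mu": 1.34, "sigma": 0.55, "units": "mV"}
      },
      "eif_cov": [
        [0.066, -0.012, 0.0047, -0.55, -0.012],
        [-0.012, 0.029, -0.099, 0.28, -0.028],
        [0.0047, -0.099, 18.0, 7.8, -0.071],
        [-0.55, 0.28, 7.8, 15.0, -0.42],
        [-0.012, -0.028, -0.071, -0.42, 0.13]
      ],
      "eif_spearman_lower": [
        [-0.41],
        [0.11, -0.22],
        [-0.48, 0.35, 0.38],
        [0.13, -0.43, -0.0016, -0.39]
      ],
      "postspike_marginals": {
        "g1": {"family": "lognormal", "mu": 14.3, "sigma": 7.5, "units": "nS"},
        "tau_g": {"family": "lognormal", "mu": 17.0, "sigma": 17.4, "units": "ms"},
        "V_T1": {"family": "lognormal", "mu": 16.2, "sigma": 4.4, "units": "mV"},
        "tau_T": {"family": "lognormal", "mu": 13.6, "sigma": 8.9, "units": "ms"},
        "E_jump": {"family": "lognormal", "mu": 15.8, "sigma": 5.7, "units": "mV"},
        "E_sag": {"family": "lognormal", "mu": 1.3, "sigma": 0.9, "units": "mV"},
        "t_sag": {"family": "lognormal", "mu": 87.5, "sigma": 23.2, "units": "ms"},
        "t_0": {"family": "lognormal", "mu": 45.9, "sigma": 15.7, "units": "ms"}
      },
      "sag_fraction": 0.32
    },
    "L4": {
      "eif_marginals": {
        "C": {"family": "lognormal", "mu": 135.0, "sigma": 36.7, "units": "pF"},
        "tau": {"family": "lognormal", "mu": 17.2, "sigma": 4.18, "units": "ms"},
        "E": {"family": "normal", "mu": -71.8, "sigma": 4.2, "units": "mV"},
        "V_T": {"family": "normal", "mu": -48.7, "sigma": 3.53, "units": "mV"},
        "Delta_T": {"family": "lognormal", "mu": 1.28, "sigma": 0.394, "units": "mV"}
      },
      "eif_cov": [
        [0.083, 0.0078, 0.25, -0.25, -0.01],
        [0.0078, 0.058, 0.28, -0.0045, -0.0066],
        [0.25, 0.28, 18.0, 5.1, -0.38],
        [-0.25, -0.0045, 5.1, 12.0, -0.38],
        [-0.01, -0.0066, -0.38, -0.38, 0.071]
      ],
      "eif_spearman_lower": [
        [0.19],
        [0.2, 0.067],
        [-0.14, -0.025, 0.29],
        [-0.13, -0.014, -0.3, -0.47]
      ],
      "postspike_marginals": {
        "g1": {"family": "lognormal", "mu": 20.0, "sigma": 9.6, "units": "nS"},
        "tau_g": {"family": "lognormal", "mu": 17.3, "sigma": 15.8, "units": "ms"},
        "V_T1": {"family": "lognormal", "mu": 15.9, "sigma": 5.1, "units": "mV"},
        "tau_T": {"family": "lognormal", "mu": 14.1, "sigma": 4.9, "units": "ms"},
        "E_jump": {"family": "lognormal", "mu": 10.1, "sigma": 3.7, "units": "mV"},
        "E_sag": {"family": "lognormal", "mu": 1.8, "sigma": 1.1, "units": "mV"},
        "t_sag": {"family": "lognormal", "mu": 66.2, "sigma": 18.9, "units": "ms"},
        "t_0": {"family": "lognormal", "mu": 30.6, "sigma": 12.2, "units": "ms"}
      },
      "sag_fraction": 0.76
    },
    "SL5": {
      "eif_marginals": {
        "C": {"family": "lognormal", "mu": 133.0, "sigma": 31.9, "units": "pF"},
        "tau": {"family": "lognormal", "mu": 18.3, "sigma": 4.74, "units": "ms"},
        "E": {"family": "normal", "mu": -69.9, "sigma": 4.18, "units": "mV"},
        "V_T": {"family": "normal", "mu": -49.7, "sigma": 3.56, "units": "mV"},
        "Delta_T": {"family": "lognormal", "mu": 1.35, "sigma": 0.523, "units": "mV"}
      },
      "eif_cov": [
        [0.063, 0.022, 0.49, -0.15, -0.02],
        [0.022, 0.065, 0.28, -0.031, -0.019],
        [0.49, 0.28, 17.0, 5.9, -0.65],
        [-0.15, -0.031, 5.9, 13.0, -0.18],
        [-0.02, -0.019, -0.65, -0.18, 0.13]
      ],
      "eif_spearman_lower": [
        [0.34],
        [0.49, 0.14],
        [-0.22, -0.086, 0.35],
        [-0.2, -0.21, -0.23, -0.039]
      ],
      "postspike_marginals": {
        "g1": {"family": "lognormal", "mu": 15.7, "sigma": 7.7, "units": "nS"},
        "tau_g": {"family": "lognormal", "mu": 23.3, "sigma": 23.9, "units": "ms"},
        "V_T1": {"family": "lognormal", "mu": 13.1, "sigma": 4.0, "units": "mV"},
        "tau_T": {"family": "lognormal", "mu": 16.4, "sigma": 9.7, "units": "ms"},
        "E_jump": {"family": "lognormal", "mu": 9.6, "sigma": 4.3, "units": "mV"},
        "E_sag": {"family": "lognormal", "mu": 2.7, "sigma": 1.7, "units": "mV"},
        "t_sag": {"family": "lognormal", "mu": 53.0, "sigma": 19.9, "units": "ms"},
        "t_0": {"family": "lognormal", "mu": 21.6, "sigma": 12.0, "units": "ms"}
      },
      "sag_fraction": 0.69
    },
    "TL5": {
      "eif_marginals": {
        "C": {"family": "lognormal", "mu": 284.0, "sigma": 78.5, "units": "pF"},
        "tau": {"family": "lognormal", "mu": 18.7, "sigma": 4.23, "units": "ms"},
        "E": {"family": "normal", "mu": -68.5, "sigma": 3.98, "units": "mV"},
        "V_T": {"family": "normal", "mu": -52.7, "sigma": 3.59, "units": "mV"},
        "Delta_T": {"family": "lognormal", "mu": 1.16, "sigma": 0.479, "units": "mV"}
      },
      "eif_cov": [
        [0.075, 0.004, 0.16, -0.28, -0.021],
        [0.004, 0.052, 0.07, -0.0054, -0.017],
        [0.16, 0.07, 16.0, 5.3, 0.22],
        [-0.28, -0.0054, 5.3, 13.0, 0.25],
        [-0.021, -0.017, 0.22, 0.25, 0.13]
      ],
      "eif_spearman_lower": [
        [0.031],
        [0.16, 0.066],
        [-0.33, 0.088, 0.29],
        [-0.2, -0.07, 0.18, 0.27]
      ],
      "postspike_marginals": {
        "g1": {"family": "lognormal", "mu": 26.1, "sigma": 12.5, "units": "nS"},
        "tau_g": {"family": "lognormal", "mu": 24.5, "sigma": 21.8, "units": "ms"},
        "V_T1": {"family": "lognormal", "mu": 14.8, "sigma": 4.4, "units": "mV"},
        "tau_T": {"family": "lognormal", "mu": 12.7, "sigma": 5.3, "units": "ms"},
        "E_jump": {"family": "lognormal", "mu": 7.9, "sigma": 4.6, "units": "mV"},
        "E_sag": {"family": "lognormal", "mu": 4.4, "sigma": 2.0, "units": "mV"},
        "t_sag": {"family": "lognormal", "mu": 40.4, "sigma": 11.5, "units": "ms"},
        "t_0": {"family": "lognormal", "mu": 11.5, "sigma": 6.8, "units": "ms"}
      },
      "sag_fraction": 0.94
    }
  }
}
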