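{
  "hybrid": {
    "nonuser": {
      "alpha": {"loc": 0.6, "scale": 0.15, "low": 0.1, "high": 0.95},
      "beta": {"loc": 1.0, "scale": 0.3, "low": 0.3, "high": 2.5},
      "lam": {"loc": 0.5, "scale": 0.15, "low": 0.05, "high": 0.95},
      "w_low": {"loc": 0.35, "scale": 0.1, "low": 0.02, "high": 0.98},
      "w_high": {"loc": 0.55, "scale": 0.1, "low": 0.02, "high": 0.98},
      "pi": {"loc": 0.1, "scale": 0.1, "low": -1.0, "high": 1.0},
      "rho": {"loc": 0.0, "scale": 0.1, "low": -1.0, "high": 1.0}
    },
    "user": {
      "alpha": {"loc": 0.6, "scale": 0.15, "low": 0.1, "high": 0.95},
      "beta": {"loc": 1.0, "scale": 0.3, "low": 0.3, "high": 2.5},
      "lam": {"loc": 0.5, "scale": 0.15, "low": 0.05, "high": 0.95},
      "w_low": {"loc": 0.45, "scale": 0.1, "low": 0.02, "high": 0.98},
      "w_high": {"loc": 0.45, "scale": 0.1, "low": 0.02, "high": 0.98},
      "pi": {"loc": 0.1, "scale": 0.1, "low": -1.0, "high": 1.0},
      "rho": {"loc": 0.0, "scale": 0.1, "low": -1.0, "high": 1.0}
    }
  },
  "utility": {
    "nonuser": {
      "mu_low": {"loc": 0.2, "scale": 0.15, "low": -1.5, "high": 1.5},
      "mu_high": {"loc": 0.7, "scale": 0.2, "low": -1.5, "high": 1.5},
      "beta_u": {"loc": 1.5, "scale": 0.3, "low": 0.5, "high": 3.0},
      "eta": {"loc": 0.3, "scale": 0.1, "low": 0.05, "high": 0.7},
      "gamma_disc": {"loc": 0.9, "scale": 0.05, "low": 0.6, "high": 1.0},
      "delta_limit": {"loc": 5.0, "scale": 1.0, "low": 1.0, "high": 9.0}
    },
    "user": {
      "mu_low": {"loc": 0.3, "scale": 0.15, "low": -1.5, "high": 1.5},
      "mu_high": {"loc": 0.45, "scale": 0.2, "low": -1.5, "high": 1.5},
      "beta_u": {"loc": 1.5, "scale": 0.3, "low": 0.5, "high": 3.0},
      "eta": {"loc": 0.3, "scale": 0.1, "low": 0.05, "high": 0.7},
      "gamma_disc": {"loc": 0.9, "scale": 0.05, "low": 0.6, "high": 1.0},
      "delta_limit": {"loc": 5.0, "scale": 1.0, "low": 1.0, "high": 9.0}
    }
  }
}
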