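{
  "description": "Printed parameters of the published three-layer attention model and its analyses. Scaled-down package defaults differ only where noted in docs/methods.md; every value here is reachable through NetworkConfig / decoder arguments.",
  "orientation_map": {"column_spacing": 0.2},
  "stimulus": {
    "n_pixels": 25,
    "envelope_sigma": 0.2,
    "wavelength": 0.6,
    "phase": 0.0,
    "ou_tau_ms": 40.0,
    "ou_sigma": 3.5
  },
  "l4": {"mean_on_rate_hz": 10.0, "off_rate_hz": 5.0},
  "network": {
    "alpha_ffwd3": 0.05,
    "ffwd3_strengths": "[JeF3, JiF3] = gamma * [1, 0.4]",
    "gamma_range_mv": [20.0, 23.0],
    "mu_i_range_mv_per_ms": [0.0, 0.5],
    "dt_ms": 0.01,
    "protocol": {"off_ms": 300.0, "on_ms": 200.0, "total_ms": 20000.0}
  },
  "specific_decoder": {
    "theta0": 0.5,
    "dtheta": 0.01,
    "total_counts_per_condition": 58500
  },
  "general_decoder": {"n_orientations": 50, "total_trials": 117000},
  "pair_discrimination": {
    "delta_theta": 0.04,
    "n_orientation_pairs": 10,
    "n_samplings": 200,
    "n_units": 100,
    "mean_trials_per_theta": 2340
  },
  "factor_analysis": {"n_factors": 5, "window_ms": 200.0,
                      "mean_trials_per_condition": 2340},
  "ephys": {
    "rate_window_ms": [60.0, 260.0],
    "decoder_window_ms": [60.0, 130.0],
    "inclusion": {"min_rate_hz": 10.0, "signed_rank_p": 1e-10},
    "tukey_rsc_cut": 0.35,
    "n_days": {"monkey1": 46, "monkey2": 28},
    "block": {"change_trials": 125, "cued_fraction": 0.8,
              "uncued_median": 20, "uncued_largest": 5}
  }
}
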