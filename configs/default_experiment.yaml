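# Default configuration for `monaural-adapt run`.
# Every key is optional; omitted keys fall back to the stock model defaults.

seed: 0          # master seed; per-stage seeds are derived deterministically
hse_db: 10.0     # head-shadow magnitude (dB) for the proximal-level regressor

design:
  n_test_trials: 180      # pre/post tests: HP50/HP60/HP70 in equal numbers
  n_control_trials: 300   # control sessions: HP 45-70 dBA + LP/BB at 50/65

models:
  # Overrides for the stock listener models. Priors are given as
  # {mean_deg, sd_deg}; sd_deg may be "inf" for the uniform limit.
  plugged_pre: {}
    # azimuth_prior: {mean_deg: -40.0, sd_deg: 15.0}
    # elevation_prior: {mean_deg: 3.0, sd_deg: 12.0}
    # azimuth_sensory_sd_deg: 30.0
    # elevation_sensory_sd_hearing_deg: 5.0
    # elevation_sensory_sd_plugged_deg: 30.0
    # binaural_weight_slope: 0.05          # logistic slope (per deg azimuth)
    # perceived_ild_bias_deg: -40.0        # plug-induced azimuth attractor
    # ild_bias_level_slope_deg_per_db: -0.5  # louder -> further earward
    # decision_rule: map                   # or posterior_sample
    # motor_noise_sd_deg: 3.0
  plugged_post: {}  # when empty, derived from the training schedule end-point
  binaural: {}

training:
  n_trials: 500              # ten azimuths x 50 repeats at HP 60 dBA
  # time_constant_trials: 500.0  # exponential relaxation constant (trials)
  # azimuth_prior_start: {mean_deg: -40.0, sd_deg: 15.0}
  # azimuth_prior_end:   {mean_deg: -5.0,  sd_deg: 60.0}
  # elevation_prior_start: {mean_deg: 3.0, sd_deg: 12.0}
  # elevation_prior_end:   {mean_deg: 0.0, sd_deg: 5.0}
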