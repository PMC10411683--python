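# Full-scale analysis configuration: a 29-participant simulated cohort with
# the task's 7-block / 294-trial structure and the standard analysis
# parameters. Every value shown is the package default; override any subset.
seed: 1

simulate:
  n_participants: 29
  n_blocks: 7                 # 42 trials per block -> 294 trials
  sampling_rate_hz: 512       # set 2048 to exercise the downsampler
  channels: [Fz, FCz, Cz, Pz, EOG]
  noise_exponent: 1.0         # 1/f background slope
  noise_scale_uv: 10.0        # broadband rms of the background
  theta_center_hz: 5.5
  theta_mean_db: {AV-AV: 4.0, AP-AP: 0.0}   # injected condition gap
  theta_trial_sd_db: 2.0
  theta_base_amp_uv: 10.0
  rt_intercept_ms: {AV-AV: 5774.0, AP-AP: 4601.0}   # condition mean RTs
  rt_theta_slope_ms_per_db: {AV-AV: -205.0, AP-AP: -94.0}
  rt_noise_sd_ms: 1000.0
  rt_participant_sd_ms: 1000.0
  rt_effect_sd_ms: 800.0      # between-participant spread of the AV-AP gap
  artifact_rate: 0.05
  artifact_amp_uv: 200.0

preprocess:
  target_rate_hz: 512
  highpass_hz: 0.1            # half-amplitude cutoff, zero-phase Butterworth
  filter_order: 2
  erp_lowpass_hz: 30          # applied to the averaged ERP
  erp_epoch_ms: [-500, 2000]
  erp_baseline_ms: [-500, 0]
  tf_epoch_ms: [-1000, 4000]  # long epochs avoid wavelet edge artifacts
  response_epoch_ms: [-500, 500]
  reject_threshold_uv: 100    # per-participant moving-window peak-to-peak
  reject_width_ms: 100
  reject_step_ms: 50
  max_rejected_fraction: 0.25 # exclude participants above this (strict >)

tfr:
  f_min: 3
  f_max: 40
  n_freqs: 38                 # log-spaced grid
  c_min: 3                    # wavelet cycles at f_min ...
  c_max: 8                    # ... rising logarithmically to f_max
  baseline_ms: [-1000, 0]     # all pre-stimulus timepoints, per condition
  band_hz: [3.2, 7.7]         # theta summary band (13 grid bins)
  window_ms: [0, 3000]        # theta summary window

stats:
  n_permutations: 1000
  cluster_forming_alpha: 0.05
  cluster_decimate: 1         # keep the full 512 Hz time course
  rt_outlier_k_sd: 3          # per-participant RT exclusion
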