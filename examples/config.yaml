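# Demo pipeline configuration: a 37-subject two-occasion cohort with
# contamination rates in the ballpark of a real screening study.
cohort:
  n_subjects: 37
  legs: [left, right]
  occasions: 2
  sigma2_p: 75.0        # between-subject variance of the true angle (deg^2)
  sigma2_o: 5.0         # between-occasion variance (deg^2)
  sigma2_res: 20.0      # residual variance (deg^2)
  mean_angle_down: 4.0  # medial-positive (deg)
  mean_angle_up: 1.0
  occasion_shift: 0.0   # systematic T2 change (deg), 0 = none
  sensor_noise_sd: 0.15 # cm, on the horizontal knee coordinate
  squat_depth: 15.0     # cm
  samples_per_phase: 30 # 1 s per phase at 30 Hz
  rater_error_prob: 0.1
  label_threshold: 6.0  # deg of medial displacement rated "fail"
  easy_mode_rate: 0.10
  missing_rate: 0.03
  seed: 1
cutoffs: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
ndigits: 2
write_trajectory_files: false
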