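cell:
  alpha_max: 0.8115631671944858
  delta_a: 0.21124027241124674
  n_vesicles: 2000
  noise_sd: 5.0
  p_release: 0.01
  quench_ratio: 20.0
  slope_m: 0.008063618808028096
  surface_frac: 0.0
  tau1: 42.79215845423684
  tau_pers: 20.0
  tau_reacid: 2.5
condition_factors:
  ca_slope_factor: 6.714306766973055
  egta_residual_alpha: 0.1
  egta_slow_factor: 1.5
fit:
  baseline_mode: fixed_zero
  min_points: 4
  offset_t0: 2.5
  window_len: 60.0
  window_mode: tail
population:
  slope_cv: 0.3
  tau1_cv: 0.2
temperature: 37C
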