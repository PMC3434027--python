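lineage:
  v0: 1.0
  p0_max: 1.0
  gamma_W: 4.0
  gamma_B: 5.0
  n: 2.0
  m: 2.0
  d1_max: 0.35
  d1_profile: apex_localized
  d1_floor_frac: 0.1
  cell_motility: 5.0e-06
morphogen:
  D_W: 1.6e-07
  D_I: 9.6e-06
  D_B: 1.26e-06
  mu0: 0.00012
  mu1: 0.00025
  alpha_W: 0.114
  alpha_I: 0.012
  beta_W: 1.0
  beta_I: 16.0
  beta_W_inh: 1.0
  n_W: 2.0
  m_W: 2.0
  n_I: 2.0
  d_W: 0.002
  d_I: 0.004
  d_B: 0.0014
geometry:
  epsilon0: 0.01
  baseline_b: 0.0
  endpoint_a:
  - -0.1
  - 0.0
  endpoint_b:
  - 0.1
  - 0.0
  flow_rate: 50.0
  flow_in_x: false
  cap_rate: 2.0
  depth_gain: 0.15
  energy_kind: tanh_wells
  segment_threshold_frac: 0.1
numerics:
  n_points: 256
  L0: 0.2
  dt: 0.001
  t_end: 100.0
  positivity_tol: 1.0e-08
  positivity_grace: 1.0
  qss_tol: 1.0e-08
  qss_max_iter: 60000
  qss_include_advection: false
  seed: 0
  snapshot_every: 5.0
  steady_tol: 1.0e-06
  extinction_floor: 0.0001
  steady_window: 1.0
  filter_cutoff: 0.6666666666666666
  strict_nonnegative: false
scenario:
  name: formation
  options: {}
source: null
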