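# Default pipeline configuration.  Units: SI internally; angles are degrees
# in all files and CLI options.  The anthropometric regression fractions used
# for subject scaling are recorded verbatim below for reproducibility.
subject:
  profile: healthy        # healthy | sci
  mass_kg: 72.0
  height_m: 1.72
devices:
  orthosis_thigh: {mass: 1.5, inertia: null}   # null -> slender-rod inertia
  orthosis_shank: {mass: 1.3, inertia: null}
  crutch: {mass: 0.8, inertia: null}
anthropometric_fractions:
  length_of_height:
    pelvis: 0.100
    torso: 0.188
    thigh: 0.245
    shank: 0.246
    foot_height: 0.039
    foot_length: 0.152
    upperarm: 0.186
    forearm: 0.146
    crutch_below_hand: 0.560
  mass_of_body:
    pelvis: 0.142
    torso: 0.436
    thigh: 0.100
    shank: 0.061
    upperarm: 0.028
    forearm: 0.022
contact:
  foot:
    stiffness: 3.0e+4            # N/m per element
    damping_coeff: 1.0           # s/m
    friction_coeff: 0.8
    slip_smoothing_velocity: 0.05  # m/s
  crutch:
    hertz_stiffness: 1.0e+6      # N/m^1.5
    damping_coeff: 1.0
    friction_coeff: 0.8
    slip_smoothing_velocity: 0.05
cost:
  # selected predictive cost: lumbar mechanical power, all-segment angular
  # momentum, knee motor torque + jerk / torque-change regularization
  terms: [lumbar_mech_power, angular_momentum, motor_torque, jerk, torque_change]
  w_reg: 0.01
ocp:
  n_mesh_swing: 2
  n_mesh_support: 1
  scheme: trapezoidal
  residual_tolerance: [1.0, 1.0]   # N, N m
  slip_velocity_bound: 0.05        # m/s
  speed_tolerance: 0.05            # m/s
  cycle_duration_rel_tol: 0.2
  stride_length_rel_tol: 0.2
  phase_fraction_abs_tol: 0.05
  default_torque_bound: 150.0      # N m
  knee_motor_bound: 34.0           # N m (orthosis motor peak torque)
  hip_capacity_fraction: 0.8
  maxiter: 3000
  time_limit: 900.0
synthetic:
  cycle_duration: 4.4              # s
  stride_length: 0.51              # m
  phase_fractions:
    support_1: 0.11
    swing_crutch_l: 0.12
    support_2: 0.11
    swing_leg_r: 0.16
    support_3: 0.11
    swing_crutch_r: 0.12
    support_4: 0.11
    swing_leg_l: 0.16
  hip_bump_deg: 22.0
  torso_lean_deg: 7.0
  crutch_lead_m: 0.15
  noise_sd: 0.0
sweep:
  k_a_deg: [20, 30, 40, 50]
  fixed: {k_s: 0.0, k_w: 0.0}
seed: 42
log_level: info
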