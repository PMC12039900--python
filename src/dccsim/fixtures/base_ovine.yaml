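schema_version: 1
params:
  hr_per_min: 91.0
  stressed_blood_volume_ml: 1100.0
  lv:
    ees_mmhg_per_ml: 1.0
    v0_ml: 5.56
    alpha_per_ml: 0.0588
    beta_mmhg: 0.3
    tmax_s: 0.26
    tau_s: 0.045
    activation_delay_s: 0.1054945054945055
  rv:
    ees_mmhg_per_ml: 1.5
    v0_ml: 19.0
    alpha_per_ml: 0.0495
    beta_mmhg: 4.5
    tmax_s: 0.26
    tau_s: 0.045
    activation_delay_s: 0.1054945054945055
  la:
    ees_mmhg_per_ml: 0.35
    v0_ml: 3.0
    alpha_per_ml: 0.06
    beta_mmhg: 0.45
    tmax_s: 0.07032967032967033
    tau_s: 0.035
    activation_delay_s: 0.0
  ra:
    ees_mmhg_per_ml: 0.15
    v0_ml: 3.0
    alpha_per_ml: 0.06
    beta_mmhg: 0.4
    tmax_s: 0.07032967032967033
    tau_s: 0.035
    activation_delay_s: 0.0
  systemic:
    rc_mmhg_s_per_ml: 0.038
    ra_mmhg_s_per_ml: 0.72
    ca_ml_per_mmhg: 1.3
    cv_ml_per_mmhg: 40.0
    rv_mmhg_s_per_ml: 0.055
  pulmonary:
    rc_mmhg_s_per_ml: 0.008
    ra_mmhg_s_per_ml: 0.035
    ca_ml_per_mmhg: 2.6
    cv_ml_per_mmhg: 9.0
    rv_mmhg_s_per_ml: 0.012
  valves:
    mitral_mmhg_s_per_ml: 0.005
    aortic_mmhg_s_per_ml: 0.005
    tricuspid_mmhg_s_per_ml: 0.005
    pulmonic_mmhg_s_per_ml: 0.005
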