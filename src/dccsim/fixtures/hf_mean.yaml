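# Heart-failure cohort mean hemodynamic targets (esmolol-induced
# biventricular failure, ovine; n = 12 samples).  SDs describe the
# cohort spread for the seeded target sampler.
schema_version: 1
label: hf_mean
base: base_ovine
targets:
  hr_per_min: 91
  lvef_pct: 29
  co_l_per_min: 1.91
  cvp_mmhg: 14
  pcwp_mmhg: 15
  pasp_mmhg: 22
  padp_mmhg: 14
  mpap_mmhg: 16
  sbp_mmhg: 49
  dbp_mmhg: 33
  map_mmhg: 38
  sd:
    hr_per_min: 3
    lvef_pct: 3
    co_l_per_min: 0.22
    cvp_mmhg: 2
    pcwp_mmhg: 2
    pasp_mmhg: 3
    padp_mmhg: 3
    mpap_mmhg: 2
    sbp_mmhg: 3
    dbp_mmhg: 5
    map_mmhg: 4
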