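# Healthy (pre-heart-failure) cohort mean hemodynamic targets
# (ovine; n = 4 animals).
schema_version: 1
label: baseline_mean
base: base_ovine
targets:
  hr_per_min: 109
  lvef_pct: 50
  co_l_per_min: 4.09
  cvp_mmhg: 10
  pcwp_mmhg: 13
  pasp_mmhg: 24
  padp_mmhg: 13
  mpap_mmhg: 17
  sbp_mmhg: 82
  dbp_mmhg: 60
  map_mmhg: 67
  sd:
    hr_per_min: 18
    lvef_pct: 0
    co_l_per_min: 1.00
    cvp_mmhg: 3
    pcwp_mmhg: 3
    pasp_mmhg: 5
    padp_mmhg: 3
    mpap_mmhg: 3
    sbp_mmhg: 7
    dbp_mmhg: 12
    map_mmhg: 10
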