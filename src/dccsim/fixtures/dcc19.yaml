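# Effective-assist device setting: 19 mm Hg systolic plateau
# (amplitude 23 mm Hg over a 4 mm Hg diastolic deflate offset).
# systolic_duration_s omitted: resolved so the decline completes at
# 1.5 * tmax of the ventricles it assists.
schema_version: 1
assist:
  amplitude_mmhg: 23
  offset_mmhg: 4
  rise_time_s: 0.10
  decline_time_s: 0.05
  trigger_delay_s: 0.02
  enabled: true
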