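# Canonical simulation scenarios for the EGFR network model.
# Doses are nM of EGF; the reference dose is 100 nM.  Structural variants
# are applied before pre-equilibration; events are (time_min, variant)
# discontinuities.
transient:
  stimulus: {species: EGF, dose_nM: 100.0, mode: pulse}
  t_end_min: 60.0
  variants: []
sustained:
  stimulus: {species: EGF, dose_nM: 100.0, mode: clamp}
  t_end_min: 120.0
  variants: [remove_internalization, clamp_EGF]
acute_inactivation:
  stimulus: {species: EGF, dose_nM: 100.0, mode: clamp}
  t_end_min: 1800.0
  variants: [remove_internalization, clamp_EGF]
  events:
    - {time_min: 360.0, kind: inhibit_EGFR_at_time, leak_factor: 1.0e-4}
crosstalk_removed:
  base: [sustained, acute_inactivation]
  extra_variants: [remove_crosstalk_AKT_ASK1]
ros_removed:
  base: [sustained, acute_inactivation]
  extra_variants: [remove_ROS]
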