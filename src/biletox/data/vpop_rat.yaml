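# Rat virtual population specification (191 individuals when reproducing
# the published scenarios). Same variability structure as the human
# population; acceptance window scaled to the rat's lower toxic bile acid
# exposure.
n_default: 191
specs:
  - {parameter_path: bsep_vmax, distribution: lognormal, location: 1.0, scale: 0.30, lower_bound: 0.30, upper_bound: 3.0}
  - {parameter_path: ntcp_vmax, distribution: lognormal, location: 1.0, scale: 0.25, lower_bound: 0.40, upper_bound: 2.5}
  - {parameter_path: baso_vmax, distribution: lognormal, location: 1.0, scale: 0.30, lower_bound: 0.30, upper_bound: 3.0}
  - {parameter_path: ba_synthesis, distribution: lognormal, location: 1.0, scale: 0.25, lower_bound: 0.40, upper_bound: 2.5}
acceptance_ranges:
  liver_toxic_ba_um: [0.2, 15.0]
  systemic_toxic_ba_um: [0.05, 20.0]
  baseline_min_atp_mm: [1.90, 2.05]
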