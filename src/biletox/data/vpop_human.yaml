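# Human virtual population specification (331 individuals when reproducing
# the published scenarios). Variability is placed on the bile acid transport
# capacities and CDCA synthesis rate, lognormal around the baseline with
# bounds wide enough to span the plausible physiologic range; candidates are
# accepted only if their drug-free baseline liver and systemic toxic bile
# acid exposure falls in the documented plausibility window.
n_default: 331
specs:
  - {parameter_path: bsep_vmax, distribution: lognormal, location: 1.0, scale: 0.30, lower_bound: 0.30, upper_bound: 3.0}
  - {parameter_path: ntcp_vmax, distribution: lognormal, location: 1.0, scale: 0.25, lower_bound: 0.40, upper_bound: 2.5}
  - {parameter_path: baso_vmax, distribution: lognormal, location: 1.0, scale: 0.30, lower_bound: 0.30, upper_bound: 3.0}
  - {parameter_path: ba_synthesis, distribution: lognormal, location: 1.0, scale: 0.25, lower_bound: 0.40, upper_bound: 2.5}
acceptance_ranges:
  liver_toxic_ba_um: [1.0, 30.0]
  systemic_toxic_ba_um: [0.2, 40.0]
  # healthy at baseline: the drug-free diurnal ATP trough stays within ~5%
  # of the species setpoint
  baseline_min_atp_mm: [3.98, 4.30]
# The four PK variability terms layered on top for the PK-variability
# scenario (normal, mean 1, truncated): oral absorption coefficient, liver
# uptake Vmax, and major/minor metabolite formation Vmax multipliers.
pk_specs:
  - {parameter_path: oral_absorption, distribution: normal, location: 1.0, scale: 0.20, lower_bound: 0.40, upper_bound: 1.8}
  - {parameter_path: liver_uptake_vmax, distribution: normal, location: 1.0, scale: 0.25, lower_bound: 0.40, upper_bound: 2.0}
  - {parameter_path: metabolite_major_vmax, distribution: normal, location: 1.0, scale: 0.25, lower_bound: 0.30, upper_bound: 2.0}
  - {parameter_path: metabolite_minor_vmax, distribution: normal, location: 1.0, scale: 0.25, lower_bound: 0.30, upper_bound: 2.0}
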