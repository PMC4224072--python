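# Bile-acid toxicity and hepatocyte injury parameters.
# The per-class Hill signal parameters (vmax_s, km_s, hill, tau) play the role
# of the in-vitro-fitted ATP-decline constants; the published fits are not in
# the public record, so these are this package's own calibrated values
# (docs/methods.md): LCA-class is the more potent toxin (lower km_s, higher
# vmax_s), and km_s sits well above the drug-free liver toxic bile acid
# concentration so baseline ATP holds its calibrated value.
# k_atp_per_h sets the ATP turnover rate; k_synth = k_usage =
# baseline_atp * k_atp so the drug-free fixed point is the species baseline.
k_atp_per_h: 1.0
classes:
  CDCA: {vmax_s: 2.5, km_s_um: 60.0, hill: 3.0, tau_per_h: 0.3}
  LCA: {vmax_s: 4.0, km_s_um: 25.0, hill: 3.0, tau_per_h: 0.3}
injury:
  # necrosis switches on below 55% of baseline ATP with a quadratic hazard
  atp_death_threshold_fraction: 0.55
  k_necrosis_max_per_h: 0.04
  necrosis_hill: 2.0
  # serum ALT fold released per unit liver fraction necrosed: killing ~1%
  # of hepatocytes transiently raises serum ALT ~3-fold
  alt_release_fold_per_fraction: 300.0
  k_alt_clear_per_h: 0.015
  k_bili_clear_per_h: 0.05
  k_regen_per_h: 0.005
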