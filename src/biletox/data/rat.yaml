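# Rat physiology and toxic-bile-acid transport baseline.
# 250-g rat; transporter capacities scale from the human set by
# (0.25/70)^0.75 ~= 0.0147. The rat's toxic bile acid exposure is kept low
# relative to the human on two documented grounds: the rat pool is dominated
# by non-toxic cholic/muricholic species (small toxic_pool_fraction, low
# CDCA synthesis per liver volume) and the rat hydroxylates LCA to the
# less-toxic hyodeoxycholic acid (nonzero lca_hydroxylation_cl), a pathway
# absent in the human.
species: rat
bodyweight_kg: 0.25
liver_volume_l: 0.0103
blood_volume_l: 0.016
portal_volume_l: 0.002
q_portal_l_per_h: 0.8
q_hepatic_artery_l_per_h: 0.3
ba_synthesis_rate_umol_per_h: 0.03
toxic_pool_fraction: 0.07
lca_hydroxylation_cl_l_per_h: 0.05
gut_conversion_k_per_h: 0.02
conjugation_k_per_h: 5.0
sulfation_k_per_h: 1.0
gut_transit_k_per_h: 0.4
fecal_loss_fraction: 0.05
lca_fecal_loss_fraction: 0.30
gallbladder_empty_fraction: 0.75
meal_times_h: [0.0, 8.0, 16.0]
baseline_atp_mm: 2.0
transporters:
  vmax_umol_per_h:
    NTCP: {CDCA: 11.8, CDCA_amide: 29.4, LCA: 5.9, LCA_amide: 14.7, LCA_sulfate: 11.8}
    BSEP: {CDCA: 2.1, CDCA_amide: 9.0, LCA: 0.59, LCA_amide: 1.65, LCA_sulfate: 0.94}
    BASOLATERAL: {CDCA: 0.47, CDCA_amide: 1.18, LCA: 0.24, LCA_amide: 0.47, LCA_sulfate: 0.47}
  km_um:
    NTCP: {CDCA: 20.0, CDCA_amide: 5.0, LCA: 20.0, LCA_amide: 5.0, LCA_sulfate: 10.0}
    BSEP: {CDCA: 10.0, CDCA_amide: 8.0, LCA: 10.0, LCA_amide: 8.0, LCA_sulfate: 8.0}
    BASOLATERAL: {CDCA: 15.0, CDCA_amide: 15.0, LCA: 15.0, LCA_amide: 15.0, LCA_sulfate: 15.0}
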