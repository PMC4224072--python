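# Human physiology and toxic-bile-acid transport baseline.
# Volumes/flows: standard 70-kg adult (liver ~1.8 L, portal flow ~60 L/h,
# hepatic artery ~30 L/h). Bile acid numbers parameterize only the toxic
# (CDCA/LCA-class) share of the pool: hepatic CDCA synthesis ~12 umol/h
# (~0.23 mmol/day), ~5% fecal loss per enterohepatic pass, gallbladder
# emptying 75% at each of three daily meals. Transporter Vmax/Km were
# calibrated (docs/methods.md) so the drug-free liver toxic bile acid
# concentration settles near 4-5 uM with BSEP running close enough to
# saturation that noncompetitive inhibition can choke export.
species: human
bodyweight_kg: 70.0
liver_volume_l: 1.8
blood_volume_l: 5.4
portal_volume_l: 1.0
q_portal_l_per_h: 60.0
q_hepatic_artery_l_per_h: 30.0
ba_synthesis_rate_umol_per_h: 12.0
toxic_pool_fraction: 0.45
lca_hydroxylation_cl_l_per_h: 0.0
gut_conversion_k_per_h: 0.02
conjugation_k_per_h: 5.0
sulfation_k_per_h: 0.5
gut_transit_k_per_h: 0.25
fecal_loss_fraction: 0.05
lca_fecal_loss_fraction: 0.30
gallbladder_empty_fraction: 0.75
meal_times_h: [0.0, 8.0, 16.0]
baseline_atp_mm: 4.2
transporters:
  vmax_umol_per_h:
    NTCP: {CDCA: 400.0, CDCA_amide: 1000.0, LCA: 200.0, LCA_amide: 500.0, LCA_sulfate: 400.0}
    BSEP: {CDCA: 144.0, CDCA_amide: 610.0, LCA: 40.0, LCA_amide: 112.0, LCA_sulfate: 64.0}
    BASOLATERAL: {CDCA: 32.0, CDCA_amide: 80.0, LCA: 16.0, LCA_amide: 32.0, LCA_sulfate: 32.0}
  km_um:
    NTCP: {CDCA: 20.0, CDCA_amide: 5.0, LCA: 20.0, LCA_amide: 5.0, LCA_sulfate: 10.0}
    BSEP: {CDCA: 10.0, CDCA_amide: 8.0, LCA: 10.0, LCA_amide: 8.0, LCA_sulfate: 8.0}
    BASOLATERAL: {CDCA: 15.0, CDCA_amide: 15.0, LCA: 15.0, LCA_amide: 15.0, LCA_sulfate: 15.0}
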