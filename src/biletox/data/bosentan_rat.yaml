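# Bosentan, rat parameterization. PK structure mirrors the human file with
# rat-scaled uptake capacity; the inhibition constants switch to the rat
# vesicle values: Bsep Ki 12 uM (parent) and 8.5 uM (phenol metabolite),
# both noncompetitive, and rat Ntcp Ki 0.23 uM noncompetitive (the rat's
# uptake inhibition is far more potent than the human's).
name: bosentan
molecular_weight_g_per_mol: 551.6
ka_per_h: 0.8
f_abs: 0.5
uptake_vmax_umol_per_h_kg075: 60.0
uptake_km_um: 20.0
passive_cl_l_per_h: 0.03
biliary_cl_ml_per_h_kg075: 120.0
renal_cl_l_per_h: 0.0
v_central_l_per_kg: 0.25
v_peripheral_l_per_kg: 0.3
q_peripheral_l_per_h: 0.07
induction:
  targets: [uptake_vmax, metabolism_vmax]
  fold_max: 2.0
  k_ind_per_h: 0.01
metabolites:
  - product_name: bosentan_hydroxy
    vmax_formation_umol_per_h: 2.2
    km_formation_um: 30.0
    product_biliary_cl_ml_per_h_kg075: 150.0
    product_efflux_cl_l_per_h: 0.05
    product_v_central_l_per_kg: 0.25
    product_renal_cl_l_per_h: 0.0
    product_inhibitions: []
  - product_name: bosentan_phenol
    vmax_formation_umol_per_h: 0.55
    km_formation_um: 30.0
    product_biliary_cl_ml_per_h_kg075: 150.0
    product_efflux_cl_l_per_h: 0.05
    product_v_central_l_per_kg: 0.25
    product_renal_cl_l_per_h: 0.0
    product_inhibitions:
      - {transporter: BSEP, ki_um: 8.5, mode: noncompetitive}
inhibitions:
  - {transporter: BSEP, ki_um: 12.0, mode: noncompetitive}
  - {transporter: NTCP, ki_um: 0.23, mode: noncompetitive}
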