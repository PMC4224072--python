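# Bosentan, human parameterization. MW 551.6 g/mol; endothelin antagonist,
# 500 mg PO BID in the toxic clinical regimen. OATP-mediated hepatic uptake
# is saturable and autoinduced (bosentan induces its own uptake and
# metabolism); elimination is almost entirely metabolic via two hepatic
# pathways (hydroxy major metabolite, phenol minor metabolite; the minor
# metabolite also inhibits BSEP, Ki 8.5 uM noncompetitive). biliary_cl
# lumps biliary excretion with CYP-independent hepatic elimination, the
# share untouched by the impaired-metabolism variant. Parent BSEP Ki
# 12 uM noncompetitive; human NTCP inhibition competitive, Ki 18 uM.
name: bosentan
molecular_weight_g_per_mol: 551.6
ka_per_h: 0.6
f_abs: 0.5
uptake_vmax_umol_per_h_kg075: 19.0
uptake_km_um: 20.0
passive_cl_l_per_h: 2.0
biliary_cl_ml_per_h_kg075: 120.0
renal_cl_l_per_h: 0.0
v_central_l_per_kg: 0.25
v_peripheral_l_per_kg: 0.3
q_peripheral_l_per_h: 5.0
induction:
  targets: [uptake_vmax, metabolism_vmax]
  fold_max: 2.0
  k_ind_per_h: 0.01
metabolites:
  - product_name: bosentan_hydroxy
    vmax_formation_umol_per_h: 150.0
    km_formation_um: 30.0
    product_biliary_cl_ml_per_h_kg075: 150.0
    product_efflux_cl_l_per_h: 3.0
    product_v_central_l_per_kg: 0.25
    product_renal_cl_l_per_h: 0.0
    product_inhibitions: []
  - product_name: bosentan_phenol
    vmax_formation_umol_per_h: 36.0
    km_formation_um: 30.0
    product_biliary_cl_ml_per_h_kg075: 150.0
    product_efflux_cl_l_per_h: 3.0
    product_v_central_l_per_kg: 0.25
    product_renal_cl_l_per_h: 0.0
    product_inhibitions:
      - {transporter: BSEP, ki_um: 8.5, mode: noncompetitive}
inhibitions:
  - {transporter: BSEP, ki_um: 12.0, mode: noncompetitive}
  - {transporter: NTCP, ki_um: 18.0, mode: competitive}
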