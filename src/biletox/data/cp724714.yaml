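# CP-724,714, human parameterization. The dominant (unresolved) metabolic
# elimination is lumped into renal_cl as a systemic clearance; the explicit
# liver metabolite compartment carries only the hypothesis-bearing pathway. MW 469.5 g/mol; HER2 inhibitor dosed
# three times daily (every 8 h) in the trials that revealed liver signals.
# The parent is rapidly metabolized (limited hepatic residence); a single
# lumped liver metabolite compartment carries the hypothesis tests. In the
# baseline file the metabolite is pharmacologically inert and clears like
# the parent (biliary 50 mL/h/kg^0.75); hypothesis scenarios add metabolite
# BSEP inhibition, cut its biliary clearance to 10% of the parent value
# (5 mL/h/kg^0.75), switch inhibition mode, and add electron transport
# chain inhibition. Parent BSEP Ki 7.45 uM from the vesicle assay
# (IC50-approximated; mode undetermined, default competitive).
name: cp724714
molecular_weight_g_per_mol: 469.5
ka_per_h: 0.8
f_abs: 0.7
uptake_vmax_umol_per_h_kg075: 1.5
uptake_km_um: 10.0
passive_cl_l_per_h: 1.5
biliary_cl_ml_per_h_kg075: 50.0
renal_cl_l_per_h: 18.0
v_central_l_per_kg: 1.5
v_peripheral_l_per_kg: 1.0
q_peripheral_l_per_h: 8.0
metabolites:
  - product_name: cp724714_metabolite
    vmax_formation_umol_per_h: 12.0
    km_formation_um: 20.0
    product_biliary_cl_ml_per_h_kg075: 50.0
    product_efflux_cl_l_per_h: 0.1
    product_v_central_l_per_kg: 0.5
    product_renal_cl_l_per_h: 0.3
    product_inhibitions: []
inhibitions:
  - {transporter: BSEP, ki_um: 7.45, mode: competitive}
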