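# Telmisartan, human parameterization. MW 514.6 g/mol; angiotensin II
# receptor blocker, clinical doses 40-80 mg once daily. Large volume of
# distribution and active hepatic uptake; elimination is essentially
# complete hepatic glucuronidation, lumped here into the parent hepatic
# (biliary_cl) clearance and a systemic clearance term (renal_cl lumps
# first-pass glucuronidation; the glucuronide does not inhibit BSEP and is
# excluded from the PK model). BSEP Ki 16 uM approximated from the
# reported IC50 (mode undetermined; scenarios run both competitive and
# noncompetitive readings).
name: telmisartan
molecular_weight_g_per_mol: 514.6
ka_per_h: 1.0
f_abs: 0.5
uptake_vmax_umol_per_h_kg075: 2.0
uptake_km_um: 15.0
passive_cl_l_per_h: 3.0
biliary_cl_ml_per_h_kg075: 125.0
renal_cl_l_per_h: 25.0
v_central_l_per_kg: 2.0
v_peripheral_l_per_kg: 4.0
q_peripheral_l_per_h: 15.0
metabolites: []
inhibitions:
  - {transporter: BSEP, ki_um: 16.0, mode: noncompetitive}
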