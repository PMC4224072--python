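"""CP-724,714 hypothesis matrix: normalized LFT elevation vs steady-state AUC.

Runs the baseline individual through the five mechanistic hypotheses
(competitive parent-only; + metabolite BSEP inhibition; + poor metabolite
biliary clearance; noncompetitive; competitive + electron-transport-chain
inhibition) across a dose grid, pairing each run's day-22 AUC(0-24) of
parent drug with the peak composite LFT statistic max(ALT fold/5,
bilirubin fold/3). The expected pattern: bile acid transporter inhibition
alone leaves the statistic at its baseline (1/3) at every exposure; adding
metabolite accumulation and ETC inhibition produces dose-dependent
elevations.

Writes results/cp724714_lft_vs_auc.csv.
"""

from pathlib import Path

from biletox.scenarios import CP_HYPOTHESES, lft_vs_auc_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = lft_vs_auc_table(
    scenario_names=CP_HYPOTHESES, doses_mg=(100.0, 250.0, 400.0, 600.0)
)
table.to_csv(OUT / "cp724714_lft_vs_auc.csv", index=False)
print(table.to_string(index=False))

flat = table[table["hypothesis"] == "cp724714_baseline"]["peak_normalized_lft"]
toxic = table[table["hypothesis"] == "cp724714_etc_inhibition"]["peak_normalized_lft"]
print(
    f"\nbile-acid-only statistic stays at {flat.max():.2f} (baseline 0.33) while "
    f"the ETC + metabolite hypothesis reaches {toxic.max():.2f}"
)
print(f"wrote {OUT / 'cp724714_lft_vs_auc.csv'}")
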