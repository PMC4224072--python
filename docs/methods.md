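# Methods

`biletox` is a mechanistic simulator of bile-acid-mediated drug-induced
liver injury (DILI). It couples four submodels inside one stiff ODE system
per simulated individual: drug disposition (PBPK), bile acid enterohepatic
circulation with transporter inhibition, an ATP-decline toxicity cascade,
and hepatocyte injury with serum biomarkers. A virtual-population layer
samples physiological variability and converts per-individual outcomes into
incidence predictions.

## Drug disposition (PBPK)

The PBPK topology is deliberately minimal: gut lumen → portal blood →
liver (extracellular + intracellular) ↔ systemic blood ↔ peripheral
tissue. Only two things are consumed downstream — plasma concentration
curves (for comparison with observed PK) and the liver intracellular
concentration of each inhibitory species (which drives transporter
inhibition) — so whole-body multi-organ structure would add parameters
without adding testable behaviour.

* Oral doses are instantaneous additions to the gut lumen (IV boluses to
  central blood); absorption is first order with a fraction absorbed.
* Hepatic uptake is Michaelis–Menten (OATP/NTCP-like), passive
  liver↔blood exchange is linear and bidirectional.
* Metabolite formation is saturable on the liver intracellular parent
  concentration. Each metabolite occupies a liver pool exchanging with a
  central pool, with biliary (liver) and optional systemic clearance.
* Autoinduction (bosentan) is a single induction multiplier rising first
  order from 1 to `fold_max` with rate `k_ind`, applied to hepatic uptake
  and metabolite-formation capacities.
* Clearances and uptake capacities that scale allometrically carry
  per-kg^0.75 units; molecular weights and bodyweights are config inputs.

Bosentan's hepatic elimination is split between the two explicit metabolite
pathways (~60%) and a lumped CYP-independent hepatic clearance carried by
the `biliary_cl` term (~40%). The impaired-metabolism variant scales only
the two explicit pathways by 0.1, so a poor-metabolizer phenotype raises
exposure roughly two-fold rather than ten-fold — without the unimpaired
floor the variant would be lethal to every simulated individual, which is
neither physiologic nor consistent with the modest clinical effect of the
CYP polymorphism.

Telmisartan's glucuronide neither inhibits BSEP nor is tracked in the PK;
first-pass glucuronidation is lumped into a systemic clearance term, making
telmisartan the high-clearance compound it is. CP-724,714's dominant (and
chemically unresolved) metabolism is likewise lumped into systemic
clearance; the explicit single liver metabolite compartment carries only
the hypothesis-bearing pathway, so its formation rate is small (~2% of
dose) and its parameters (BSEP inhibition, biliary clearance, ETC potency)
are scenario knobs, not fitted constants.

## Bile acid circulation

Five species are tracked — CDCA, CDCA amide, LCA, LCA amide, LCA sulfate —
across liver intracellular, gallbladder, gut lumen, portal blood and
systemic blood pools. Non-toxic bile acids (cholate, muricholate, ...) are
outside the model; the parameter files encode only the toxic share of the
pool.

* CDCA is synthesized at a constant hepatic rate; amidation (and LCA
  sulfation) are first order in the liver.
* NTCP carries bile acids from portal blood into the hepatocyte, BSEP
  exports them to canalicular bile (routed directly to the gallbladder
  between meals — no bile duct compartment), and a lumped basolateral
  transporter (MRP3/4-like) provides an overflow route to systemic blood
  sized at roughly 10% of canalicular capacity.
* Gallbladder emptying is an instantaneous transfer of 75% of its content
  to the gut lumen at each of three daily meals; meals and (TID) dosing
  share the clock.
* Gut flora convert CDCA-class species to the corresponding LCA-class
  species first order. Gut outflow splits into fecal loss and portal
  reabsorption; the fecal share is 5% per pass for CDCA-class and 30% for
  the poorly reabsorbed LCA-class. Without that split, slow LCA export
  (small canalicular capacity) turns the gut conversion flux into an
  unbounded hepatic LCA reservoir.
* The rat — and only the rat — hydroxylates LCA-class species to
  hyodeoxycholate-like products (a liver clearance sink).
* Portal↔systemic exchange is first order with splanchnic-flow-derived
  rate constants, so systemic bile acids recirculate through the liver.

Inhibition kinetics: competitive inhibitors scale a transporter's apparent
Km by (1 + I/Ki), noncompetitive inhibitors scale apparent Vmax by
1/(1 + I/Ki); co-inhibitors of one transporter multiply their factors.
BSEP, basolateral and ETC inhibition read the liver intracellular drug
concentration; NTCP inhibition reads plasma.

## Toxicity cascade

The liver intracellular concentration of each toxicity class (CDCA-like,
LCA-like; conjugates inherit the parent's class) is low-pass filtered,
d[BA]_delay/dt = τ([BA] − [BA]_delay), and drives a Hill-type ATP-synthesis
inhibition signal per class,

    S_c = 1 / (1 + Vmax_S · [BA]_delay^H / (Km_S^H + [BA]_delay^H)),

with classes combined as a product (independent-hit assumption; a
sensitivity knob). ATP then relaxes as

    d[ATP]/dt = k_synth · S · etc − k_usage · [ATP]/[ATP]_baseline,

with k_synth = k_usage = baseline·k_atp (k_atp = 1/h), so the drug-free
fixed point is the calibrated baseline (4.2 mM human, 2.0 mM rat) and a
sustained signal S·etc = x settles ATP at x·baseline. The usage term is
proportional to ATP rather than constant: a constant-usage reading would
drive ATP negative and has no stable calibration point. `etc` is the
fractional synthesis capacity under electron-transport-chain inhibitors,
Π 1/(1 + I/Ki_ETC).

The per-class signal parameters stand in for in-vitro fitted constants that
are not publicly tabulated; the bundled values (CDCA-like: Vmax_S 2.5,
Km_S 60 µM, H 3, τ 0.3/h; LCA-like: 4.0, 25 µM, 3, 0.3/h — LCA the more
potent toxin) are this package's own calibration and are marked
non-canonical. `fit_tox_params` recovers such parameters from ATP
time-course data generated by `synthetic_data.gen_invitro_atp`, which is
how the real constants would be estimated from experiments.

## Injury and biomarkers

Below an ATP death threshold (55% of baseline) hepatocytes necrose with
hazard k_nec·deficit², where deficit is the fractional shortfall below the
threshold. Necrosis releases ALT into serum (~3-fold elevation per 1% of
the liver killed), cleared first order (t½ ≈ 2 days); the shrinking viable
fraction reduces bilirubin clearance, so serum bilirubin fold tracks
1/viable first order; slow regeneration restores the viable fraction. The
composite statistic is normalized LFT = max(ALT fold/5, bilirubin fold/3),
and the incidence criterion is peak ALT > 3× the individual's baseline
(baseline-referenced, not ULN-referenced).

These functional forms are this package's definitions. They were
calibrated jointly with the bile acid transport baseline to the documented
acceptance surface: drug-free ATP setpoints of 4.2/2.0 mM; zero ALT
elevations for telmisartan 50 mg (either inhibition mode) and for rat
bosentan across the virtual populations; at least one elevation of 331 for
human bosentan 500 mg BID.

## The toxicity mechanism, qualitatively

At baseline, canalicular export runs near enough to saturation that the
meal-triggered recycling pulses use most of the BSEP reserve. Bosentan's
noncompetitive inhibition (parent Ki 12 µM, phenol metabolite 8.5 µM)
transiently cuts export capacity two- to three-fold at liver drug peaks;
for most individuals the liver concentration rises a few-fold and relaxes,
but individuals with low sampled BSEP capacity and/or high synthesis cross
into a regime where a meal's recycled bolus cannot be re-exported, the
liver transiently traps a large share of the circulating pool, the delayed
toxic concentration crosses Km_S, ATP collapses and necrosis follows. The
first dosing day is the most dangerous: autoinduction has not yet reduced
exposure. Telmisartan at 50 mg produces liver concentrations far below its
Ki (16 µM) and perturbs nothing; the rat is protected by its small toxic
pool share and the hydroxylation sink even though its Ntcp is potently
inhibited — eliminating rat uptake inhibition (Ki → 1e10) raises liver
bile acid accumulation but still produces no injury, reproducing the
species-difference argument.

CP-724,714 itself clears the liver too fast to matter; toxicity requires
its metabolite to accumulate (biliary clearance 10% of parent) and to
inhibit the ETC. With bile acid inhibition alone — competitive or
noncompetitive — the composite LFT statistic stays at baseline across the
dose grid; adding ETC inhibition (Ki 6 µM, a hypothesis parameter)
produces dose-dependent elevations, augmented by the concurrent bile acid
accumulation.

## Virtual populations

Candidates draw lognormal multiplicative overrides on BSEP, NTCP and
basolateral Vmax and on CDCA synthesis (CV 25–30%, bounded); each
candidate's drug-free baseline is solved (warm-started from the reference
baseline and verified periodic day-over-day) and accepted only if baseline
liver and systemic toxic bile acid exposure falls in the documented
plausibility windows and the drug-free diurnal ATP trough stays within ~5%
of the species setpoint — an individual whose baseline is already
injurious is not a plausible healthy subject. 331 humans / 191 rats are the reference population
sizes; arbitrary n is supported. PK variability (four truncated-normal
multipliers: oral absorption, hepatic uptake Vmax, major and minor
metabolite formation Vmax) can be layered on an existing population, and
is applied to the full 331 (whether the original "small" population was a
subset is not recoverable; the discrepancy is noted). Everything is
reproducible from integer seeds.

## Numerics

The coupled system (37 bile-acid/toxicity states plus up to 18 PK states)
is integrated with LSODA (through `scipy.integrate.odeint`, whose wrapper
releases its Fortran work arrays between the many event segments of a
population study) and a hand-derived analytic Jacobian (verified against
finite differences in the test suite) at rtol 1e-6 / atol 1e-9;
meal emptying and dose administrations are exact inter-segment state
jumps, which keeps the right-hand side smooth and the step count low. Mole
conservation (bile acids: d(total) = synthesis − fecal − hydroxylation)
and drug mass conservation (administered = compartments + elimination
sinks) are audited on every trace and hold to ~1e-13, far inside the 1e-6
requirement. Small negative amounts within absolute tolerance are clipped
at segment boundaries and counted; anything beyond −1e-6 µmol aborts the
run with a diagnostic naming the state. Baseline solves integrate ≥30 days
from an empty system (12 days when warm-started) and must show <0.5%
day-over-day change in every compartment holding ≥0.1% of the pool.

## Synthetic data

All fitting routines are exercised against generators with known ground
truth: noisy plasma PK curves (stand-ins for literature concentration-time
data and the non-public rat PK dataset), clamped-exposure ATP time courses
(the in-vitro toxicity experiment), and ±ATP vesicle plates with duplicate
wells and the documented serial dilution. Default measurement noise is
proportional: 5% (PK), 5% (ATP), 3% (plates). The generators share the
simulation code with the fitters only where the model itself is the
quantity being fitted (self-consistency); recovery tolerances in the test
suite are 15% (PK), 20% (toxicity), 15% (IC50) at those noise levels and
0.1% noise-free. What passing these tests shows is that the estimation
machinery is unbiased and identifiable under the stated designs — not that
real assay data are this clean.

## Known limitations

* The calibration reproduces the published qualitative discriminations,
  not the published incidence decimals: our bosentan baseline run flags
  ~4–6% of the human population (clinically 8–18% of patients showed ALT
  elevations at this dose; the original model predicted 0.3%). The
  severity of crossing individuals is also right-shifted: once canalicular
  export chokes, the trapped-pool runaway produces deep ATP collapse, so
  peak ALT folds for responders are tens-fold rather than marginal.
* Supra-pharmacological telmisartan (3000/12000 mg) stresses the lumped
  linear clearance beyond its validity; only the dose ordering is
  meaningful there.
* No FXR feedback on synthesis, no mechanistic mitochondrial permeability
  transition, no phospholipid (MDR3) pathway, no intracellular drug
  trafficking — all documented as out of scope.
* Bilirubin handling is a pure clearance model on viable mass; transporter
  effects on bilirubin are not represented.
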