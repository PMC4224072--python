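"""Scenario registry: end-to-end dosing simulations and hypothesis matrices.

Each named scenario bundles a compound parameterization (possibly modified
by hypothesis flags: inhibition mode, metabolite activity and clearance,
electron-transport-chain inhibition, impaired metabolism, basolateral
inhibition), a dosing regimen and a species. Scenarios simulate the drug PK
once (shared across individuals unless PK variability is present), then
drive the bile acid/ATP/injury engine per individual, with the three daily
meals of the simulated schedule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, pbpk, vpop
from .bile_acid import solve_baseline
from .compounds import (
    CompoundModel,
    DoseRegimen,
    InhibitionSpec,
    apply_impaired_metabolism,
    load_compound,
)
from .hepatotox import default_injury_params, default_tox_params
from .physiology import load_physiology

DEFAULT_ETC_KI_UM = 10.0
DEFAULT_BASOLATERAL_KI_UM = 2.0


# -- compound modifiers ----------------------------------------------------

def with_bsep_mode(compound: CompoundModel, mode: str) -> CompoundModel:
    """Set the inhibition mode of every BSEP inhibition (parent + metabolites)."""
    out = compound.copy()
    for spec in out.inhibitions:
        if spec.transporter == "BSEP":
            spec.mode = mode
    for m in out.metabolites:
        for spec in m.product_inhibitions:
            if spec.transporter == "BSEP":
                spec.mode = mode
    return out


def with_ntcp_ki(compound: CompoundModel, ki_um: float) -> CompoundModel:
    out = compound.copy()
    for spec in out.inhibitions:
        if spec.transporter == "NTCP":
            spec.ki_um = ki_um
    return out


def with_basolateral_inhibition(
    compound: CompoundModel, ki_um: float, mode: str = "noncompetitive"
) -> CompoundModel:
    out = compound.copy()
    out.inhibitions.append(
        InhibitionSpec(transporter="BASOLATERAL", ki_um=ki_um, mode=mode)
    )
    return out


def with_etc_inhibition(
    compound: CompoundModel, ki_um: float, include_metabolites: bool = True
) -> CompoundModel:
    out = compound.copy()
    out.inhibitions.append(InhibitionSpec(transporter="ETC", ki_um=ki_um))
    if include_metabolites:
        for m in out.metabolites:
            m.product_inhibitions.append(
                InhibitionSpec(transporter="ETC", ki_um=ki_um)
            )
    return out


# -- scenario --------------------------------------------------------------

@dataclass
class Scenario:
    name: str
    species: str
    compound: CompoundModel | None
    regimen: DoseRegimen | None
    follow_up_h: float = 96.0
    description: str = ""
    requires_pk_variability: bool = False

    @property
    def duration_h(self) -> float:
        if self.regimen is None:
            return 30 * 24.0
        return self.regimen.duration_h + self.follow_up_h

    def _individual_compound(self, ind) -> CompoundModel | None:
        pk_over = ind.pk_overrides()
        if not pk_over or self.compound is None:
            return None
        c = self.compound.copy()
        if "oral_absorption" in pk_over:
            c.ka_per_h *= pk_over["oral_absorption"]
        if "liver_uptake_vmax" in pk_over:
            c.uptake_vmax_umol_per_h_kg075 *= pk_over["liver_uptake_vmax"]
        if "metabolite_major_vmax" in pk_over and c.metabolites:
            c.metabolites[0].vmax_formation_umol_per_h *= pk_over[
                "metabolite_major_vmax"
            ]
        if "metabolite_minor_vmax" in pk_over and len(c.metabolites) > 1:
            c.metabolites[1].vmax_formation_umol_per_h *= pk_over[
                "metabolite_minor_vmax"
            ]
        return c

    def simulate_individual(self, ind, physiology, transporters) -> dict:
        tr_i, ph_i = vpop.apply_transport_overrides(
            transporters, physiology, ind.overrides
        )
        compound = None
        if self.compound is not None:
            compound = self._individual_compound(ind) or self.compound
        trace = engine.simulate_exposure(
            tr_i,
            ph_i,
            duration_h=self.duration_h,
            initial_state=ind.baseline_state,
            initial_atp_mm=ind.baseline_summary.get("baseline_atp_mm"),
            compound=compound,
            regimen=self.regimen if compound is not None else None,
        )
        return summarize_trace(trace, ind.baseline_summary)

    def simulate_baseline_individual(self, context=None) -> engine.ExposureTrace:
        """Run the unperturbed baseline individual through this scenario."""
        ctx = context or baseline_context(self.species)
        return engine.simulate_exposure(
            ctx["transporters"],
            ctx["physiology"],
            ctx["tox"],
            ctx["injury"],
            duration_h=self.duration_h,
            initial_state=ctx["baseline_state"],
            initial_atp_mm=ctx["baseline_atp_mm"],
            compound=self.compound,
            regimen=self.regimen if self.compound is not None else None,
        )


def summarize_trace(trace: engine.ExposureTrace, baseline_summary=None) -> dict:
    out = {
        "min_atp_mm": trace.min_atp_mm(),
        "peak_alt_fold": trace.peak_alt_fold(),
        "peak_bili_fold": trace.peak_bili_fold(),
        "peak_normalized_lft": trace.peak_normalized_lft(),
        "peak_liver_toxic_ba_um": float(trace.liver_toxic_conc_um().max()),
        "final_viable_fraction": float(trace.viable_fraction[-1]),
        "mole_balance_error": trace.mole_balance_error(),
    }
    if baseline_summary:
        out["baseline_liver_toxic_ba_um"] = baseline_summary.get("liver_toxic_ba_um")
    return out


@lru_cache(maxsize=4)
def baseline_context(species: str) -> dict:
    """Solved drug-free baseline of the unperturbed individual, cached."""
    physiology, transporters = load_physiology(species)
    tox = default_tox_params(physiology)
    injury = default_injury_params(physiology)
    trace = solve_baseline(transporters, physiology, tox, injury)
    return {
        "physiology": physiology,
        "transporters": transporters,
        "tox": tox,
        "injury": injury,
        "baseline_trace": trace,
        "baseline_state": trace.final_state(),
        "baseline_atp_mm": trace.final_atp_mm(),
    }


# -- registry --------------------------------------------------------------

def _bosentan_human(mod=None, name="", desc="", pk_var=False) -> Scenario:
    c = load_compound("bosentan")
    if mod is not None:
        c = mod(c)
    return Scenario(
        name=name,
        species="human",
        compound=c,
        regimen=DoseRegimen(amount_mg=500.0, interval_h=12.0, n_doses=60),
        description=desc,
        requires_pk_variability=pk_var,
    )


def _telmisartan(dose_mg: float, mode: str, name: str) -> Scenario:
    c = with_bsep_mode(load_compound("telmisartan"), mode)
    return Scenario(
        name=name,
        species="human",
        compound=c,
        regimen=DoseRegimen(amount_mg=dose_mg, interval_h=24.0, n_doses=30),
        description=f"telmisartan {dose_mg:g} mg once daily, {mode} BSEP inhibition",
    )


def _bosentan_rat(ntcp_ki=None, name="", desc="") -> Scenario:
    c = load_compound("bosentan_rat")
    if ntcp_ki is not None:
        c = with_ntcp_ki(c, ntcp_ki)
    return Scenario(
        name=name,
        species="rat",
        compound=c,
        regimen=DoseRegimen(amount_mg=50.0, interval_h=24.0, n_doses=30, per_kg=True),
        description=desc,
    )


def cp724714_scenario(
    name: str,
    dose_mg: float = 250.0,
    metabolite_inhibits_bsep: bool = False,
    metabolite_biliary_cl_ml_per_h_kg075: float | None = None,
    mode: str = "competitive",
    etc_inhibition: bool = False,
    etc_ki_um: float = DEFAULT_ETC_KI_UM,
    n_days: int = 30,
) -> Scenario:
    """Hypothesis-matrix builder for the CP-724,714 toxicity mechanisms."""
    c = load_compound("cp724714")
    if metabolite_inhibits_bsep:
        # metabolite inhibits BSEP with the same Ki as the parent
        parent_ki = [s.ki_um for s in c.inhibitions if s.transporter == "BSEP"][0]
        c.metabolites[0].product_inhibitions.append(
            InhibitionSpec(transporter="BSEP", ki_um=parent_ki, mode=mode)
        )
    if metabolite_biliary_cl_ml_per_h_kg075 is not None:
        c.metabolites[0].product_biliary_cl_ml_per_h_kg075 = (
            metabolite_biliary_cl_ml_per_h_kg075
        )
    c = with_bsep_mode(c, mode)
    if etc_inhibition:
        c = with_etc_inhibition(c, etc_ki_um, include_metabolites=True)
    return Scenario(
        name=name,
        species="human",
        compound=c,
        regimen=DoseRegimen(amount_mg=dose_mg, interval_h=8.0, n_doses=3 * n_days),
        description=(
            f"CP-724,714 {dose_mg:g} mg q8h, mode={mode}, "
            f"metabolite BSEP={metabolite_inhibits_bsep}, "
            f"met biliary cl={metabolite_biliary_cl_ml_per_h_kg075}, "
            f"ETC={etc_inhibition}"
        ),
    )


_POOR_CL = 5.0  # 10% of the parent's 50 mL/h/kg^0.75 biliary clearance

SCENARIO_BUILDERS = {
    "drug_free_human": lambda: Scenario(
        name="drug_free_human", species="human", compound=None, regimen=None,
        description="no drug; 30-day baseline run",
    ),
    "drug_free_rat": lambda: Scenario(
        name="drug_free_rat", species="rat", compound=None, regimen=None,
        description="no drug; 30-day baseline run",
    ),
    "bosentan_human_baseline": lambda: _bosentan_human(
        name="bosentan_human_baseline",
        desc="bosentan 500 mg q12h x30 d, baseline assumptions",
    ),
    "bosentan_human_pk_variability": lambda: _bosentan_human(
        name="bosentan_human_pk_variability",
        desc="baseline assumptions plus PK variability in the population",
        pk_var=True,
    ),
    "bosentan_human_impaired_metabolism": lambda: _bosentan_human(
        mod=lambda c: apply_impaired_metabolism(c, 0.1),
        name="bosentan_human_impaired_metabolism",
        desc="metabolite formation Vmax at 10% of baseline (poor metabolizer)",
    ),
    "bosentan_human_basolateral": lambda: _bosentan_human(
        mod=lambda c: with_basolateral_inhibition(c, DEFAULT_BASOLATERAL_KI_UM),
        name="bosentan_human_basolateral",
        desc="exploratory basolateral (MRP3/4) inhibition added to baseline",
    ),
    "bosentan_rat": lambda: _bosentan_rat(
        name="bosentan_rat", desc="bosentan 50 mg/kg once daily x30 d, rat"
    ),
    "bosentan_rat_no_uptake_inhibition": lambda: _bosentan_rat(
        ntcp_ki=1e10,
        name="bosentan_rat_no_uptake_inhibition",
        desc="rat run with Ntcp inhibition eliminated (Ki 1e10)",
    ),
    "telmisartan_50_competitive": lambda: _telmisartan(
        50.0, "competitive", "telmisartan_50_competitive"
    ),
    "telmisartan_50_noncompetitive": lambda: _telmisartan(
        50.0, "noncompetitive", "telmisartan_50_noncompetitive"
    ),
    "telmisartan_3000_noncompetitive": lambda: _telmisartan(
        3000.0, "noncompetitive", "telmisartan_3000_noncompetitive"
    ),
    "telmisartan_12000_noncompetitive": lambda: _telmisartan(
        12000.0, "noncompetitive", "telmisartan_12000_noncompetitive"
    ),
    "cp724714_baseline": lambda: cp724714_scenario("cp724714_baseline"),
    "cp724714_metabolite_inhibition": lambda: cp724714_scenario(
        "cp724714_metabolite_inhibition", metabolite_inhibits_bsep=True
    ),
    "cp724714_poor_clearance": lambda: cp724714_scenario(
        "cp724714_poor_clearance",
        metabolite_inhibits_bsep=True,
        metabolite_biliary_cl_ml_per_h_kg075=_POOR_CL,
    ),
    "cp724714_noncompetitive": lambda: cp724714_scenario(
        "cp724714_noncompetitive",
        metabolite_inhibits_bsep=True,
        metabolite_biliary_cl_ml_per_h_kg075=_POOR_CL,
        mode="noncompetitive",
    ),
    "cp724714_etc_inhibition": lambda: cp724714_scenario(
        "cp724714_etc_inhibition",
        metabolite_inhibits_bsep=True,
        metabolite_biliary_cl_ml_per_h_kg075=_POOR_CL,
        mode="competitive",
        etc_inhibition=True,
    ),
}


def list_scenarios() -> list:
    return sorted(SCENARIO_BUILDERS)


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIO_BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        ) from None


def build_population(species: str, seed: int, n: int | None = None):
    """Seeded virtual population from the bundled specification."""
    cfg = vpop.load_vpop_config(species)
    ctx = baseline_context(species)
    return vpop.generate_simpops(
        n=n or cfg["n_default"],
        specs=cfg["specs"],
        transporters=ctx["transporters"],
        physiology=ctx["physiology"],
        seed=seed,
        acceptance_ranges=cfg["acceptance_ranges"],
        tox=ctx["tox"],
        injury=ctx["injury"],
    )


def run_scenario(
    name: str,
    seed: int = 1234,
    n: int | None = None,
    out_dir=None,
    pop=None,
):
    """End-to-end: build (or reuse) the population, run, summarize, persist."""
    scenario = get_scenario(name)
    if pop is None:
        pop = build_population(scenario.species, seed=seed, n=n)
    if scenario.requires_pk_variability:
        cfg = vpop.load_vpop_config(scenario.species)
        pop = vpop.add_pk_variability(pop, cfg["pk_specs"], seed=seed + 1)
    results = vpop.run_population(pop, scenario)
    count, pct = vpop.incidence(results)
    config_digest = hashlib.sha256(
        json.dumps(
            {"scenario": scenario.description, "name": name, "seed": seed,
             "n": len(pop)},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    summary = {
        "scenario": name,
        "species": scenario.species,
        "seed": seed,
        "n": len(pop),
        "n_alt_gt_3x": count,
        "pct_alt_gt_3x": pct,
        "n_integration_failures": int((results["error"] != "").sum()),
        "min_atp_mm_median": float(results["min_atp_mm"].median()),
        "min_atp_mm_min": float(results["min_atp_mm"].min()),
        "config_digest": config_digest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / f"{name}_individuals.csv", index=False)
        (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=1))
        pop.save_manifest(out / f"{name}_population.json")
    return {"scenario": scenario, "population": pop, "results": results,
            "summary": summary}


# -- dose-response analyses (baseline individual) --------------------------

def metabolite_clearance_sweep(
    cl_values_ml_per_h_kg075=(1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
    dose_mg: float = 250.0,
    n_days: int = 30,
) -> pd.DataFrame:
    """Peak ALT fold vs metabolite biliary clearance (competitive BSEP + ETC).

    The metabolite's biliary clearance does not alter parent plasma PK, so it
    is a pure degree of freedom; this sweep quantifies its leverage on
    predicted toxicity.
    """
    if any(cl <= 0 for cl in cl_values_ml_per_h_kg075):
        raise ValueError("clearance values must be > 0")
    rows = []
    for cl in cl_values_ml_per_h_kg075:
        sc = cp724714_scenario(
            f"cp724714_sweep_cl_{cl:g}",
            dose_mg=dose_mg,
            metabolite_inhibits_bsep=True,
            metabolite_biliary_cl_ml_per_h_kg075=float(cl),
            mode="competitive",
            etc_inhibition=True,
            n_days=n_days,
        )
        trace = sc.simulate_baseline_individual()
        rows.append(
            {
                "metabolite_biliary_cl_ml_per_h_kg075": float(cl),
                "peak_alt_fold": trace.peak_alt_fold(),
                "peak_normalized_lft": trace.peak_normalized_lft(),
                "min_atp_mm": trace.min_atp_mm(),
            }
        )
    return pd.DataFrame(rows)


CP_HYPOTHESES = (
    "cp724714_baseline",
    "cp724714_metabolite_inhibition",
    "cp724714_poor_clearance",
    "cp724714_noncompetitive",
    "cp724714_etc_inhibition",
)


def lft_vs_auc_table(
    scenario_names=CP_HYPOTHESES,
    doses_mg=(100.0, 250.0, 400.0, 600.0),
    n_days: int = 30,
) -> pd.DataFrame:
    """(AUC_0-24 on day 22, peak normalized LFT) per dose per hypothesis."""
    if n_days < 22:
        raise ValueError("regimen must cover at least 22 days for the day-22 AUC")
    rows = []
    for name in scenario_names:
        template = get_scenario(name)
        for dose in doses_mg:
            if dose == 0:
                sc = get_scenario("drug_free_human")
                sc = Scenario(
                    name=f"{name}_dose_0", species="human", compound=None,
                    regimen=None,
                )
                trace = sc.simulate_baseline_individual()
                auc22 = 0.0
            else:
                sc = cp724714_scenario(
                    f"{name}_dose_{dose:g}",
                    dose_mg=dose,
                    metabolite_inhibits_bsep=any(
                        s.transporter == "BSEP"
                        for m in template.compound.metabolites
                        for s in m.product_inhibitions
                    ),
                    metabolite_biliary_cl_ml_per_h_kg075=(
                        template.compound.metabolites[0]
                        .product_biliary_cl_ml_per_h_kg075
                    ),
                    mode=next(
                        s.mode
                        for s in template.compound.inhibitions
                        if s.transporter == "BSEP"
                    ),
                    etc_inhibition=any(
                        s.transporter == "ETC" for s in template.compound.inhibitions
                    ),
                    n_days=n_days,
                )
                ctx = baseline_context("human")
                curve = pbpk.simulate_pk(
                    sc.compound, sc.regimen, ctx["physiology"], dt_out_h=0.1,
                    follow_up_h=sc.follow_up_h,
                )
                auc22 = pbpk.auc(curve, sc.compound.name, 21 * 24.0, 22 * 24.0)
                trace = sc.simulate_baseline_individual()
            rows.append(
                {
                    "hypothesis": name,
                    "dose_mg": float(dose),
                    "auc_0_24_day22_uM_h": float(auc22),
                    "peak_normalized_lft": trace.peak_normalized_lft(),
                    "peak_alt_fold": trace.peak_alt_fold(),
                }
            )
    return pd.DataFrame(rows)
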