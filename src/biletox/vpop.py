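"""Virtual populations: sampled parameter variability with plausibility filters.

A population (331 humans / 191 rats when reproducing the published
scenarios) is built by rejection sampling: candidate individuals draw
multiplicative overrides on the bile acid transport capacities and CDCA
synthesis rate, their drug-free baseline is solved, and the candidate is
accepted only if the baseline liver and systemic toxic bile acid exposure
falls inside the documented plausibility ranges. Everything is reproducible
from the integer seed. PK variability (four normal multipliers: oral
absorption, liver uptake Vmax, major/minor metabolite formation Vmax) can be
layered on top of an existing population.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine
from .bile_acid import TransporterParams
from .physiology import SpeciesPhysiology

TRANSPORT_PATHS = ("bsep_vmax", "ntcp_vmax", "baso_vmax", "ba_synthesis")
PK_PATHS = (
    "oral_absorption",
    "liver_uptake_vmax",
    "metabolite_major_vmax",
    "metabolite_minor_vmax",
)


@dataclass
class VariabilitySpec:
    parameter_path: str
    distribution: str  # "lognormal" | "normal"
    location: float
    scale: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be lognormal or normal")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("inconsistent bounds")

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            if self.distribution == "lognormal":
                x = self.location * np.exp(rng.normal(0.0, self.scale))
            else:
                x = rng.normal(self.location, self.scale)
            if self.lower_bound <= x <= self.upper_bound:
                return float(x)
        raise RuntimeError(
            f"could not sample {self.parameter_path} within bounds "
            f"[{self.lower_bound}, {self.upper_bound}]"
        )


@dataclass
class VirtualIndividual:
    id: int
    overrides: dict
    baseline_summary: dict
    baseline_state: object = None  # BileAcidState, not serialized

    def pk_overrides(self) -> dict:
        return {k: v for k, v in self.overrides.items() if k in PK_PATHS}


@dataclass
class SimPops:
    species: str
    individuals: list
    seed: int
    acceptance_ranges: dict
    specs: list = field(default_factory=list)
    physiology: SpeciesPhysiology | None = None
    transporters: TransporterParams | None = None

    def __len__(self) -> int:
        return len(self.individuals)

    def manifest(self) -> dict:
        return {
            "species": self.species,
            "seed": self.seed,
            "n": len(self.individuals),
            "acceptance_ranges": self.acceptance_ranges,
            "specs": [dataclasses.asdict(s) for s in self.specs],
            "individuals": [
                {
                    "id": i.id,
                    "overrides": i.overrides,
                    "baseline_summary": i.baseline_summary,
                }
                for i in self.individuals
            ],
        }

    def save_manifest(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.manifest(), indent=1))


def apply_transport_overrides(
    transporters: TransporterParams,
    physiology: SpeciesPhysiology,
    overrides: dict,
):
    """Return (transporters, physiology) copies with multipliers applied."""
    tr = transporters.copy()
    ph = physiology.copy()
    for path, mult in overrides.items():
        if path == "bsep_vmax":
            tr.vmax_umol_per_h["BSEP"] = tr.vmax_umol_per_h["BSEP"] * mult
        elif path == "ntcp_vmax":
            tr.vmax_umol_per_h["NTCP"] = tr.vmax_umol_per_h["NTCP"] * mult
        elif path == "baso_vmax":
            tr.vmax_umol_per_h["BASOLATERAL"] = (
                tr.vmax_umol_per_h["BASOLATERAL"] * mult
            )
        elif path == "ba_synthesis":
            ph.ba_synthesis_rate_umol_per_h *= mult
        elif path in PK_PATHS:
            continue
        else:
            raise KeyError(f"unknown override path {path!r}")
    return tr, ph


def load_vpop_config(species: str) -> dict:
    text = (
        resources.files("biletox.data").joinpath(f"vpop_{species}.yaml").read_text()
    )
    d = yaml.safe_load(text)
    d["specs"] = [VariabilitySpec(**s) for s in d["specs"]]
    if "pk_specs" in d:
        d["pk_specs"] = [VariabilitySpec(**s) for s in d["pk_specs"]]
    return d


def _baseline_observables(trace: engine.ExposureTrace) -> dict:
    # diurnal averages (and the ATP trough) over the final simulated day
    mask = trace.times_h >= trace.times_h[-1] - 24.0
    return {
        "liver_toxic_ba_um": float(trace.liver_toxic_conc_um()[mask].mean()),
        "systemic_toxic_ba_um": float(trace.systemic_conc_um()[mask].mean()),
        "baseline_min_atp_mm": float(trace.atp_mm[mask].min()),
        "baseline_atp_mm": float(trace.atp_mm[-1]),
    }


def solve_individual_baseline(
    transporters,
    physiology,
    tox=None,
    injury=None,
    warm_start=None,
    tol: float = 0.005,
):
    """Drug-free periodic steady state of one (possibly perturbed) individual.

    ``warm_start`` (a BileAcidState near the attractor) shortens the settle
    time; convergence is still verified day-over-day and extended if needed.
    """
    days = 12 if warm_start is not None else 30
    trace = engine.simulate_exposure(
        transporters, physiology, tox, injury,
        duration_h=days * 24.0, initial_state=warm_start,
    )
    total_days = days
    while not trace.is_periodic(tol) and total_days < 90:
        total_days += 12
        trace = engine.simulate_exposure(
            transporters, physiology, tox, injury,
            duration_h=total_days * 24.0, initial_state=warm_start,
        )
    if not trace.is_periodic(tol):
        raise engine.IntegrationError("individual baseline failed to settle")
    return trace


def generate_simpops(
    n: int,
    specs: list,
    transporters: TransporterParams,
    physiology: SpeciesPhysiology,
    seed: int,
    acceptance_ranges: dict,
    tox=None,
    injury=None,
    min_acceptance_rate: float = 0.01,
    progress: bool = False,
) -> SimPops:
    """Rejection-sample ``n`` accepted individuals, reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not specs:
        raise ValueError("at least one VariabilitySpec required")
    from .bile_acid import solve_baseline

    rng = np.random.default_rng(seed)
    reference = solve_baseline(transporters, physiology, tox, injury)
    warm = reference.final_state()

    individuals = []
    attempts = 0
    failures = 0
    while len(individuals) < n:
        attempts += 1
        if attempts > 50 and (len(individuals) / attempts) < min_acceptance_rate:
            raise RuntimeError(
                f"virtual population acceptance rate "
                f"{len(individuals)}/{attempts} fell below "
                f"{min_acceptance_rate:.0%}; acceptance_ranges="
                f"{acceptance_ranges}, last failures={failures}"
            )
        overrides = {s.parameter_path: s.sample(rng) for s in specs}
        tr_i, ph_i = apply_transport_overrides(transporters, physiology, overrides)
        try:
            trace = solve_individual_baseline(
                tr_i, ph_i, tox, injury, warm_start=warm
            )
        except engine.IntegrationError:
            failures += 1
            continue
        obs = _baseline_observables(trace)
        ok = all(
            lo <= obs[key] <= hi for key, (lo, hi) in acceptance_ranges.items()
        )
        if not ok:
            failures += 1
            continue
        individuals.append(
            VirtualIndividual(
                id=len(individuals),
                overrides=overrides,
                baseline_summary=obs,
                baseline_state=trace.final_state(),
            )
        )
        if progress and len(individuals) % 50 == 0:
            print(f"  accepted {len(individuals)}/{n} ({attempts} attempts)")
    return SimPops(
        species=physiology.species,
        individuals=individuals,
        seed=seed,
        acceptance_ranges=acceptance_ranges,
        specs=list(specs),
        physiology=physiology,
        transporters=transporters,
    )


def add_pk_variability(pop: SimPops, pk_specs: list, seed: int) -> SimPops:
    """Layer the four PK multipliers on top of an existing population."""
    names = {s.parameter_path for s in pk_specs}
    if names != set(PK_PATHS):
        raise ValueError(
            f"pk_specs must name exactly {sorted(PK_PATHS)}, got {sorted(names)}"
        )
    rng = np.random.default_rng(seed)
    new_inds = []
    for ind in pop.individuals:
        pk_over = {s.parameter_path: s.sample(rng) for s in pk_specs}
        new_inds.append(
            VirtualIndividual(
                id=ind.id,
                overrides={**ind.overrides, **pk_over},
                baseline_summary=dict(ind.baseline_summary),
                baseline_state=ind.baseline_state,
            )
        )
    return SimPops(
        species=pop.species,
        individuals=new_inds,
        seed=seed,
        acceptance_ranges=pop.acceptance_ranges,
        specs=list(pop.specs) + list(pk_specs),
        physiology=pop.physiology,
        transporters=pop.transporters,
    )


def run_population(pop: SimPops, scenario) -> pd.DataFrame:
    """Run a scenario over every individual; one row per individual.

    Individual integration failures are recorded (``error`` column) and the
    run continues. Results depend only on each individual's parameters, so
    they are identical regardless of execution order.
    """
    rows = []
    for ind in pop.individuals:
        try:
            summary = scenario.simulate_individual(
                ind, pop.physiology, pop.transporters
            )
            summary["error"] = ""
        except engine.IntegrationError as exc:
            summary = {"error": str(exc)}
        rows.append({"individual_id": ind.id, **summary})
    return pd.DataFrame(rows)


def incidence(results: pd.DataFrame, alt_fold_threshold: float = 3.0):
    """(count, percentage) of individuals with peak ALT fold above threshold."""
    if len(results) == 0:
        raise ValueError("empty result table")
    flags = results["peak_alt_fold"] > alt_fold_threshold
    count = int(flags.sum())
    return count, 100.0 * count / len(results)
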