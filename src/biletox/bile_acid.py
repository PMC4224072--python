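"""Bile acid synthesis, conjugation and enterohepatic recirculation.

The model tracks the two potentially toxic primary/secondary bile acids,
chenodeoxycholic acid (CDCA) and lithocholic acid (LCA), together with their
amide conjugates (and the sulfate conjugate of LCA), across five anatomical
pools: liver intracellular, gallbladder, gut lumen, portal blood and systemic
blood. Non-toxic bile acids (cholic, muricholic, ...) are outside the model;
the documented species parameter sets encode how large the toxic share of the
pool is in each organism.

Transport fluxes are Michaelis-Menten: NTCP carries bile acids from portal
blood into the hepatocyte, BSEP exports them into canalicular bile (routed to
the gallbladder between meals), and a lumped basolateral transporter
(MRP3/4-like) provides an overflow route from hepatocyte to systemic blood.
Gallbladder emptying is an instantaneous meal-triggered transfer. Gut flora
convert CDCA species to the more toxic LCA species; the rat (but not the
human) additionally detoxifies LCA by hydroxylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed species enumeration (order matters: it indexes all parameter arrays).
BA_SPECIES = ("CDCA", "CDCA_amide", "LCA", "LCA_amide", "LCA_sulfate")
# Toxicity class of each species: conjugates inherit the parent's class.
BA_CLASS = ("CDCA", "CDCA", "LCA", "LCA", "LCA")
TOXICITY_CLASSES = ("CDCA", "LCA")
COMPARTMENTS = (
    "liver_intracellular",
    "gallbladder",
    "gut_lumen",
    "portal_blood",
    "systemic_blood",
)
N_SPECIES = len(BA_SPECIES)
N_COMPARTMENTS = len(COMPARTMENTS)

SPECIES_INDEX = {s: i for i, s in enumerate(BA_SPECIES)}
COMPARTMENT_INDEX = {c: i for i, c in enumerate(COMPARTMENTS)}


def toxicity_class(species: str) -> str:
    return BA_CLASS[SPECIES_INDEX[species]]


@dataclass
class BileAcidState:
    """Molar amounts (µmol) of each species in each compartment, plus the
    delayed liver-intracellular concentrations (µM) that drive toxicity."""

    amounts_umol: np.ndarray = field(
        default_factory=lambda: np.zeros((N_SPECIES, N_COMPARTMENTS))
    )
    delayed_liver_conc_um: np.ndarray = field(
        default_factory=lambda: np.zeros(N_SPECIES)
    )

    def __post_init__(self) -> None:
        self.amounts_umol = np.asarray(self.amounts_umol, dtype=float)
        self.delayed_liver_conc_um = np.asarray(
            self.delayed_liver_conc_um, dtype=float
        )
        if self.amounts_umol.shape != (N_SPECIES, N_COMPARTMENTS):
            raise ValueError("amounts must have shape (species, compartments)")
        if (self.amounts_umol < -1e-9).any():
            raise ValueError("bile acid amounts must be non-negative")

    def copy(self) -> "BileAcidState":
        return BileAcidState(
            self.amounts_umol.copy(), self.delayed_liver_conc_um.copy()
        )

    def amount(self, species: str, compartment: str) -> float:
        return float(
            self.amounts_umol[SPECIES_INDEX[species], COMPARTMENT_INDEX[compartment]]
        )

    def liver_conc_um(self, liver_volume_l: float) -> np.ndarray:
        return self.amounts_umol[:, 0] / liver_volume_l

    def total_umol(self) -> float:
        return float(self.amounts_umol.sum())

    def to_frame(self, time_h: float = 0.0):
        import pandas as pd

        rows = []
        for s in range(N_SPECIES):
            for c in range(N_COMPARTMENTS):
                rows.append(
                    {
                        "time_h": time_h,
                        "species": BA_SPECIES[s],
                        "compartment": COMPARTMENTS[c],
                        "amount_umol": self.amounts_umol[s, c],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class TransporterParams:
    """Per-species Vmax (µmol/h) and Km (µM) for each bile acid transporter."""

    vmax_umol_per_h: dict
    km_um: dict

    def __post_init__(self) -> None:
        for tr in ("NTCP", "BSEP", "BASOLATERAL"):
            if tr not in self.vmax_umol_per_h or tr not in self.km_um:
                raise ValueError(f"missing transporter {tr}")
            self.vmax_umol_per_h[tr] = _as_species_array(self.vmax_umol_per_h[tr])
            self.km_um[tr] = _as_species_array(self.km_um[tr])
            if (self.vmax_umol_per_h[tr] < 0).any():
                raise ValueError("vmax must be >= 0")
            if (self.km_um[tr] <= 0).any():
                raise ValueError("km must be > 0")

    def copy(self) -> "TransporterParams":
        return TransporterParams(
            {k: v.copy() for k, v in self.vmax_umol_per_h.items()},
            {k: v.copy() for k, v in self.km_um.items()},
        )

    def scaled(self, transporter: str, factor: float) -> "TransporterParams":
        out = self.copy()
        out.vmax_umol_per_h[transporter] = out.vmax_umol_per_h[transporter] * factor
        return out


def _as_species_array(value) -> np.ndarray:
    if isinstance(value, dict):
        return np.array([float(value[s]) for s in BA_SPECIES])
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(N_SPECIES, float(arr))
    if arr.shape != (N_SPECIES,):
        raise ValueError("per-species parameter must have one entry per species")
    return arr


# -- operations ------------------------------------------------------------

def ba_fluxes(
    state: BileAcidState,
    transporters: TransporterParams,
    physiology,
    inhibitor_liver_conc_um=None,
    inhibitor_plasma_conc_um=None,
    inhibition_specs=None,
):
    """Net d(amount)/dt (µmol/h) for every species/compartment, plus sinks.

    This is the readable reference for the flux laws; the compiled kernel in
    :mod:`biletox.engine` evaluates the same expressions inside the ODE solve
    (the test suite checks the two paths against each other). Inhibitors are
    given as parallel lists of liver and plasma concentrations with their
    InhibitionSpec lists (one list per chemical species of each compound).

    Returns ``(deriv, sinks)`` where ``deriv`` has shape (species,
    compartments) and ``sinks`` is a dict with the instantaneous synthesis,
    fecal-loss and hydroxylation rates (µmol/h), so that
    d(total)/dt = synthesis - fecal - hydroxylation.
    """
    from . import engine

    y = engine.state_to_vector(state, atp_mm=physiology.baseline_atp_mm)
    p = engine.pack_params(
        transporters,
        physiology,
        tox=None,
        injury=None,
        inhibitors=inhibition_specs or [],
    )
    n_inh = len(inhibition_specs or [])
    if n_inh:
        liv = np.array(
            [[float(c)] for c in inhibitor_liver_conc_um], dtype=float
        )
        pla = np.array(
            [[float(c)] for c in (inhibitor_plasma_conc_um or inhibitor_liver_conc_um)],
            dtype=float,
        )
        tgrid = np.array([0.0])
    else:
        tgrid = np.array([0.0])
        liv = np.zeros((0, 1))
        pla = np.zeros((0, 1))
    dy = engine.rhs(0.0, y, p, tgrid, liv, pla)
    deriv = dy[: N_SPECIES * N_COMPARTMENTS].reshape(N_SPECIES, N_COMPARTMENTS)
    sinks = {
        "synthesis_umol_per_h": float(dy[engine.IDX_SYNTH]),
        "fecal_umol_per_h": float(dy[engine.IDX_FECAL]),
        "hydroxylation_umol_per_h": float(dy[engine.IDX_HYDROX]),
    }
    return deriv, sinks


def gallbladder_empty(state: BileAcidState, physiology, t_h: float = 0.0) -> BileAcidState:
    """Meal-triggered gallbladder contraction.

    Transfers ``gallbladder_empty_fraction`` of each species' gallbladder
    content to the gut lumen; total moles are conserved exactly.
    """
    out = state.copy()
    frac = physiology.gallbladder_empty_fraction
    moved = out.amounts_umol[:, COMPARTMENT_INDEX["gallbladder"]] * frac
    out.amounts_umol[:, COMPARTMENT_INDEX["gallbladder"]] -= moved
    out.amounts_umol[:, COMPARTMENT_INDEX["gut_lumen"]] += moved
    return out


def solve_baseline(
    transporters: TransporterParams,
    physiology,
    tox=None,
    injury=None,
    n_days: int = 30,
    max_days: int = 120,
    tol: float = 0.005,
):
    """Drug-free periodic steady state under the daily meal schedule.

    Integrates at least ``n_days`` simulated days from an empty system (bile
    acids build up from synthesis) and requires the day-over-day relative
    change of every compartment total to fall below ``tol``. Returns an
    :class:`~biletox.engine.ExposureTrace` whose final state is the pre-dose
    initial condition used everywhere else.

    Raises ``RuntimeError`` with the trailing trajectory attached if the
    system has not settled after ``max_days``.
    """
    from . import engine
    from .hepatotox import default_injury_params, default_tox_params

    tox = tox or default_tox_params(physiology)
    injury = injury or default_injury_params(physiology)
    trace = engine.simulate_exposure(
        transporters,
        physiology,
        tox,
        injury,
        duration_h=n_days * 24.0,
        initial_state=None,
    )
    while not trace.is_periodic(tol) and trace.times_h[-1] < max_days * 24.0:
        trace = engine.simulate_exposure(
            transporters,
            physiology,
            tox,
            injury,
            duration_h=trace.times_h[-1] + 10 * 24.0,
            initial_state=None,
        )
    if not trace.is_periodic(tol):
        raise RuntimeError(
            "baseline did not reach a periodic steady state within "
            f"{max_days} days; trailing compartment totals: "
            f"{trace.daily_compartment_totals()[-5:]}"
        )
    return trace
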