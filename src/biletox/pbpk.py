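"""Minimal lumped PBPK model for drug and metabolite liver/plasma exposure.

Compartment topology: gut lumen → portal blood → liver (extracellular +
intracellular) ↔ systemic blood ↔ peripheral tissue. Hepatic uptake is
saturable (Michaelis-Menten, autoinducible), passive liver↔blood exchange is
bidirectional and linear, metabolite formation is saturable on the liver
intracellular parent concentration, and elimination occurs by biliary
(liver), renal (central) and metabolite-specific clearances. Oral doses are
instantaneous additions to the gut lumen; IV doses go to central blood.

Only plasma fits and liver exposure are consumed downstream, which is why
the topology is deliberately small: it reproduces oral concentration-time
curves (including bosentan's autoinduction and metabolites) and yields the
liver intracellular concentrations that drive transporter inhibition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .compounds import CompoundModel, DoseRegimen
from .physiology import SpeciesPhysiology

# fraction of anatomical liver volume treated as extracellular (sinusoidal +
# interstitial) vs hepatocyte intracellular water
LIVER_EC_FRACTION = 0.2

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class PKIntegrationError(RuntimeError):
    pass


@dataclass
class PKCurve:
    """Plasma and liver concentration time courses for parent + metabolites."""

    times_h: np.ndarray
    plasma_um: dict  # species name -> µM array
    liver_um: dict  # species name -> µM array (intracellular for the parent)
    administered_umol: np.ndarray | None = None
    total_umol: np.ndarray | None = None
    clip_events: int = 0

    @property
    def species(self) -> list:
        return list(self.plasma_um)

    def mass_balance_error(self) -> float:
        """Max relative |administered − (compartments + sinks)| over time."""
        if self.administered_umol is None:
            raise ValueError("curve carries no mass audit")
        denom = np.maximum(self.administered_umol, 1e-12)
        return float(
            np.max(np.abs(self.administered_umol - self.total_umol) / denom)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            for comp, series in (("plasma", self.plasma_um[sp]), ("liver", self.liver_um[sp])):
                rows.append(
                    pd.DataFrame(
                        {
                            "time_h": self.times_h,
                            "species": sp,
                            "compartment": comp,
                            "conc_uM": series,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PKCurve":
        times = np.sort(df["time_h"].unique())
        plasma, liver = {}, {}
        for sp, sub in df.groupby("species"):
            for comp, target in (("plasma", plasma), ("liver", liver)):
                s = sub[sub["compartment"] == comp].sort_values("time_h")
                if len(s):
                    target[sp] = np.interp(times, s["time_h"], s["conc_uM"])
        return cls(times_h=times, plasma_um=plasma, liver_um=liver)


def _volumes(compound: CompoundModel, phys: SpeciesPhysiology):
    v_le = LIVER_EC_FRACTION * phys.liver_volume_l
    v_lic = (1.0 - LIVER_EC_FRACTION) * phys.liver_volume_l
    v_c = compound.v_central_l_per_kg * phys.bodyweight_kg
    v_per = max(compound.v_peripheral_l_per_kg * phys.bodyweight_kg, 1e-9)
    return v_le, v_lic, v_c, v_per


def _rhs_factory(compound: CompoundModel, phys: SpeciesPhysiology):
    v_le, v_lic, v_c, v_per = _volumes(compound, phys)
    v_portal = phys.portal_volume_l
    q_pv = phys.q_portal_l_per_h
    q_ha = phys.q_hepatic_artery_l_per_h
    q_h = q_pv + q_ha
    kg075 = phys.allometric_kg075
    up_vmax = compound.uptake_vmax_umol_per_h_kg075 * kg075
    up_km = compound.uptake_km_um
    pas = compound.passive_cl_l_per_h
    bil = compound.biliary_cl_ml_per_h_kg075 * kg075 / 1000.0
    ren = compound.renal_cl_l_per_h
    qp = compound.q_peripheral_l_per_h
    ka = compound.ka_per_h
    f_abs = compound.f_abs
    mets = compound.metabolites
    nm = len(mets)
    ind = compound.induction
    k_ind = ind.k_ind_per_h if ind else 0.0
    fold_max = ind.fold_max if ind else 1.0
    ind_up = bool(ind and "uptake_vmax" in ind.targets)
    ind_met = bool(ind and "metabolism_vmax" in ind.targets)
    m_vmax = np.array([m.vmax_formation_umol_per_h for m in mets])
    m_km = np.array([m.km_formation_um for m in mets])
    m_bil = np.array(
        [m.product_biliary_cl_ml_per_h_kg075 * kg075 / 1000.0 for m in mets]
    )
    m_eff = np.array([m.product_efflux_cl_l_per_h for m in mets])
    m_ren = np.array([m.product_renal_cl_l_per_h for m in mets])
    m_vc = np.array(
        [max(m.product_v_central_l_per_kg * phys.bodyweight_kg, 1e-9) for m in mets]
    )
    v_liver = phys.liver_volume_l

    def rhs(t, y):
        G, P, LE, LIC, C, PER, E = y[:7]
        cP = P / v_portal
        cLE = LE / v_le
        cLIC = LIC / v_lic
        cC = C / v_c
        cPER = PER / v_per
        e_up = E if ind_up else 1.0
        e_met = E if ind_met else 1.0
        absorbed = ka * G
        uptake = e_up * up_vmax * cLE / (up_km + cLE) if up_vmax > 0 else 0.0
        passive = pas * (cLE - cLIC)
        met_flux = e_met * m_vmax * cLIC / (m_km + cLIC) if nm else np.zeros(0)
        dy = np.zeros_like(y)
        dy[0] = -absorbed
        dy[1] = f_abs * absorbed + q_pv * cC - q_pv * cP
        dy[2] = q_pv * cP + q_ha * cC - q_h * cLE - uptake - passive
        dy[3] = uptake + passive - met_flux.sum() - bil * cLIC
        dy[4] = q_h * cLE - (q_pv + q_ha) * cC - ren * cC - qp * (cC - cPER)
        dy[5] = qp * (cC - cPER)
        dy[6] = k_ind * (fold_max - E)
        # sinks: fecal (unabsorbed), biliary, renal
        dy[7 + 2 * nm] = (1.0 - f_abs) * absorbed
        dy[7 + 2 * nm + 1] = bil * cLIC
        dy[7 + 2 * nm + 2] = ren * cC
        for j in range(nm):
            Ml = y[7 + 2 * j]
            Mc = y[7 + 2 * j + 1]
            cMl = Ml / v_liver
            cMc = Mc / m_vc[j]
            exch = m_eff[j] * (cMl - cMc)
            dy[7 + 2 * j] = met_flux[j] - m_bil[j] * cMl - exch
            dy[7 + 2 * j + 1] = exch - m_ren[j] * cMc
            dy[7 + 2 * nm + 3 + 2 * j] = m_bil[j] * cMl
            dy[7 + 2 * nm + 3 + 2 * j + 1] = m_ren[j] * cMc
        return dy

    return rhs, nm


def simulate_pk(
    compound: CompoundModel,
    regimen: DoseRegimen,
    physiology: SpeciesPhysiology,
    dt_out_h: float = 0.1,
    follow_up_h: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> PKCurve:
    """Simulate repeated dosing; returns dense plasma/liver curves with a mass audit."""
    rhs, nm = _rhs_factory(compound, physiology)
    nstate = 10 + 4 * nm
    y = np.zeros(nstate)
    y[6] = 1.0  # induction multiplier starts uninduced
    dose = regimen.dose_umol(compound, physiology.bodyweight_kg)
    dose_times = regimen.dose_times_h
    t_end = regimen.duration_h + follow_up_h
    events = sorted(set(dose_times + [0.0, t_end]))

    v_le, v_lic, v_c, v_per = _volumes(compound, physiology)
    names = compound.species_names()
    ts = [np.array([0.0])]
    ys = [y.copy()[None, :]]
    administered = [0.0]
    given = 0.0
    clip_events = 0
    for t0, t1 in zip(events[:-1], events[1:]):
        if t0 in dose_times:
            if regimen.route == "oral":
                y[0] += dose
            else:
                y[4] += dose
            given += dose
            administered[-1] = given
            ys[-1][-1] = y  # re-record post-dose state at this time point
        if t1 <= t0:
            continue
        n_samp = max(int(np.ceil((t1 - t0) / dt_out_h)), 2)
        t_eval = np.linspace(t0, t1, n_samp + 1)
        sol_y, info = odeint(
            rhs, y, t_eval, rtol=rtol, atol=atol, tfirst=True, mxstep=10000,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            worst = int(np.argmin(sol_y[-1]))
            raise PKIntegrationError(
                f"PK integration failed in [{t0:.2f}, {t1:.2f}] h "
                f"(state index {worst}): {info['message']}"
            )
        y = sol_y[-1].copy()
        amounts = y[:6]
        if amounts.min() < 0:
            if amounts.min() < -1e-6:
                raise PKIntegrationError(
                    f"negative drug amount beyond tolerance at t={t1:.2f} h"
                )
            y[:6] = np.clip(amounts, 0.0, None)
            clip_events += 1
        ts.append(t_eval[1:])
        ys.append(sol_y[1:])
        administered.extend([given] * (len(t_eval) - 1))

    times = np.concatenate(ts)
    Y = np.vstack(ys)
    administered = np.array(administered)
    # mass audit: everything except the induction state is drug mass
    total = Y[:, :6].sum(axis=1) + Y[:, 7:].sum(axis=1)

    plasma = {names[0]: Y[:, 4] / v_c}
    liver = {names[0]: Y[:, 3] / v_lic}
    for j, m in enumerate(compound.metabolites):
        mvc = max(m.product_v_central_l_per_kg * physiology.bodyweight_kg, 1e-9)
        plasma[m.product_name] = Y[:, 7 + 2 * j + 1] / mvc
        liver[m.product_name] = Y[:, 7 + 2 * j] / physiology.liver_volume_l
    return PKCurve(
        times_h=times,
        plasma_um=plasma,
        liver_um=liver,
        administered_umol=administered,
        total_umol=total,
        clip_events=clip_events,
    )


def auc(curve: PKCurve, species: str, t_start_h: float, t_end_h: float) -> float:
    """Trapezoidal AUC (µM·h) of plasma concentration over [t_start, t_end]."""
    if species not in curve.plasma_um:
        raise KeyError(f"species {species!r} not in curve ({curve.species})")
    if not t_start_h < t_end_h:
        raise ValueError("t_start must be < t_end")
    t = curve.times_h
    if t_start_h < t[0] - 1e-9 or t_end_h > t[-1] + 1e-9:
        raise ValueError("AUC window outside the simulated range")
    c = curve.plasma_um[species]
    mask = (t > t_start_h) & (t < t_end_h)
    tt = np.concatenate([[t_start_h], t[mask], [t_end_h]])
    cc = np.concatenate(
        [[np.interp(t_start_h, t, c)], c[mask], [np.interp(t_end_h, t, c)]]
    )
    return float(np.trapezoid(cc, tt))


# -- fitting ---------------------------------------------------------------

_PARAM_ALIASES = {
    "ka": "ka_per_h",
    "f_abs": "f_abs",
    "uptake_vmax": "uptake_vmax_umol_per_h_kg075",
    "uptake_km": "uptake_km_um",
    "passive_cl": "passive_cl_l_per_h",
    "biliary_cl": "biliary_cl_ml_per_h_kg075",
    "renal_cl": "renal_cl_l_per_h",
    "v_central": "v_central_l_per_kg",
    "v_peripheral": "v_peripheral_l_per_kg",
    "q_peripheral": "q_peripheral_l_per_h",
}
_MET_RE = re.compile(r"metabolites\[(\d+)\]\.(\w+)")
_MET_ALIASES = {
    "vmax_formation": "vmax_formation_umol_per_h",
    "km_formation": "km_formation_um",
    "product_biliary_cl": "product_biliary_cl_ml_per_h_kg075",
}


def get_param(compound: CompoundModel, path: str) -> float:
    m = _MET_RE.fullmatch(path)
    if m:
        j, name = int(m.group(1)), m.group(2)
        return getattr(compound.metabolites[j], _MET_ALIASES.get(name, name))
    return getattr(compound, _PARAM_ALIASES.get(path, path))


def set_param(compound: CompoundModel, path: str, value: float) -> None:
    m = _MET_RE.fullmatch(path)
    if m:
        j, name = int(m.group(1)), m.group(2)
        setattr(compound.metabolites[j], _MET_ALIASES.get(name, name), value)
        return
    setattr(compound, _PARAM_ALIASES.get(path, path), value)


@dataclass
class PKFitResult:
    compound: CompoundModel
    success: bool
    at_bounds: bool
    cost: float
    message: str
    params: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.success and not self.at_bounds


def fit_pk(
    observed: pd.DataFrame,
    compound_template: CompoundModel,
    free_params: list,
    bounds: dict,
    regimen: DoseRegimen,
    physiology: SpeciesPhysiology,
    weight_floor_um: float = 0.05,
) -> PKFitResult:
    """Weighted least-squares PK parameter estimation.

    ``observed`` holds plasma samples (columns time_h, species, conc_uM);
    residuals are scaled by max(observation, ``weight_floor_um``) so peaks and
    tails contribute comparably. The fit is deterministic given the template
    as initial guess. Non-convergence or a solution pinned at a bound is
    flagged, never silent.
    """
    from scipy.optimize import least_squares

    n_obs = len(observed)
    if n_obs < 2 * len(free_params):
        raise ValueError(
            f"need >= {2 * len(free_params)} observations for {len(free_params)} "
            f"free parameters, got {n_obs}"
        )
    lo = np.array([bounds[p][0] for p in free_params], dtype=float)
    hi = np.array([bounds[p][1] for p in free_params], dtype=float)
    x0 = np.clip(
        np.array([get_param(compound_template, p) for p in free_params], dtype=float),
        lo,
        hi,
    )
    obs_by_species = {
        sp: (sub["time_h"].to_numpy(), sub["conc_uM"].to_numpy())
        for sp, sub in observed.groupby("species")
    }
    t_max = float(observed["time_h"].max())
    follow = max(0.0, t_max - regimen.duration_h) + 1e-6

    def residuals(x):
        c = compound_template.copy()
        for pth, v in zip(free_params, x):
            set_param(c, pth, float(v))
        try:
            curve = simulate_pk(
                c, regimen, physiology, dt_out_h=0.25, follow_up_h=follow,
                rtol=1e-7, atol=1e-9,
            )
        except PKIntegrationError:
            return np.full(n_obs, 1e3)
        res = []
        for sp, (tt, cc) in obs_by_species.items():
            pred = np.interp(tt, curve.times_h, curve.plasma_um[sp])
            res.append((pred - cc) / np.maximum(cc, weight_floor_um))
        return np.concatenate(res)

    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", x_scale=np.maximum(x0, 1e-6),
        max_nfev=200 * len(free_params),
    )
    fitted = compound_template.copy()
    for pth, v in zip(free_params, sol.x):
        set_param(fitted, pth, float(v))
    span = np.maximum(hi - lo, 1e-12)
    at_bounds = bool(
        np.any((sol.x - lo) / span < 1e-4) or np.any((hi - sol.x) / span < 1e-4)
    )
    return PKFitResult(
        compound=fitted,
        success=bool(sol.success),
        at_bounds=at_bounds,
        cost=float(sol.cost),
        message=str(sol.message),
        params={p: float(v) for p, v in zip(free_params, sol.x)},
    )
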