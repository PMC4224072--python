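"""Synthetic dataset generators with known ground truth.

Every fitting routine in the package (PK parameter estimation, in-vitro
toxicity parameter fitting, vesicle IC50 fitting) has a matching generator
here that simulates the corresponding experiment from known parameters and
adds seeded measurement noise, returning a (dataset, truth) pair. These
stand in for the literature concentration-time curves and the non-public rat
PK dataset the real models were fitted against, and make end-to-end
parameter-recovery testing possible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import DEFAULT_SERIAL_DILUTION_UM, VesiclePlate
from .compounds import CompoundModel, DoseRegimen
from .hepatotox import ClassToxParams, simulate_invitro_atp
from .pbpk import simulate_pk
from .physiology import SpeciesPhysiology


@dataclass
class NoiseModel:
    """Measurement noise: proportional (CV), additive (SD), or both."""

    kind: str = "proportional"
    cv: float = 0.05
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError("kind must be proportional, additive or combined")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("cv and sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(values, dtype=float).copy()
        if self.kind in ("proportional", "combined") and self.cv > 0:
            v = v * (1.0 + rng.normal(0.0, self.cv, size=v.shape))
        if self.kind in ("additive", "combined") and self.sd > 0:
            v = v + rng.normal(0.0, self.sd, size=v.shape)
        return np.clip(v, 0.0, None)


def gen_plasma_pk(
    true_compound: CompoundModel,
    regimen: DoseRegimen,
    physiology: SpeciesPhysiology,
    sample_times_h,
    noise: NoiseModel,
    species: list | None = None,
):
    """Noisy plasma concentration samples plus the generating truth.

    Returns (DataFrame[time_h, species, conc_uM], truth dict).
    """
    rng = np.random.default_rng(noise.seed)
    sample_times_h = np.asarray(sample_times_h, dtype=float)
    follow = max(0.0, float(sample_times_h.max()) - regimen.duration_h) + 1e-6
    curve = simulate_pk(
        true_compound, regimen, physiology, dt_out_h=0.1, follow_up_h=follow
    )
    species = species or [true_compound.name]
    frames = []
    for sp in species:
        clean = np.interp(sample_times_h, curve.times_h, curve.plasma_um[sp])
        frames.append(
            pd.DataFrame(
                {
                    "time_h": sample_times_h,
                    "species": sp,
                    "conc_uM": noise.apply(clean, rng),
                }
            )
        )
    truth = {
        "compound": true_compound.to_dict(),
        "noise": dataclasses_dict(noise),
    }
    return pd.concat(frames, ignore_index=True), truth


def gen_invitro_atp(
    true_tox: ClassToxParams,
    ba_class: str,
    exposure_levels_um,
    times_h,
    noise: NoiseModel,
    baseline_atp_mm: float = 4.2,
    k_atp_per_h: float = 1.0,
):
    """ATP (% of control) time courses at clamped intracellular bile acid levels.

    Emulates the in-vitro experiment the toxicity submodel is fitted to:
    hepatocytes exposed so that the intracellular concentration of one bile
    acid class is held at each level while ATP is tracked.
    """
    exposure_levels_um = list(exposure_levels_um)
    if len(exposure_levels_um) < 2:
        raise ValueError("need >= 2 exposure levels")
    rng = np.random.default_rng(noise.seed)
    times_h = np.asarray(times_h, dtype=float)
    rows = []
    for e in exposure_levels_um:
        clean = simulate_invitro_atp(
            true_tox, float(e), times_h, baseline_atp_mm, k_atp_per_h
        )
        rows.append(
            pd.DataFrame(
                {
                    "ba_class": ba_class,
                    "exposure_um": float(e),
                    "time_h": times_h,
                    "atp_pct": noise.apply(clean, rng),
                }
            )
        )
    truth = {
        "params": dataclasses_dict(true_tox),
        "baseline_atp_mm": baseline_atp_mm,
        "k_atp_per_h": k_atp_per_h,
    }
    return pd.concat(rows, ignore_index=True), truth


def gen_vesicle_assay(
    true_ic50_um: float,
    true_hill: float = 1.0,
    max_inhibition_pct: float = 97.0,
    dilution_series_um=DEFAULT_SERIAL_DILUTION_UM,
    noise: NoiseModel | None = None,
    top_signal: float = 100.0,
    background_signal: float = 5.0,
    n_replicates: int = 2,
):
    """Simulated ±ATP vesicle plate with logistic inhibition of net uptake.

    The IC50 is expressed on the same (nominal) concentration scale as the
    dilution series. Wells are duplicated per the documented protocol.
    """
    noise = noise or NoiseModel(kind="proportional", cv=0.03, seed=0)
    rng = np.random.default_rng(noise.seed)
    conc = np.asarray(dilution_series_um, dtype=float)
    floor = 1.0 - max_inhibition_pct / 100.0
    inhib = conc ** true_hill / (conc ** true_hill + true_ic50_um ** true_hill)
    net_true = top_signal * (1.0 - (1.0 - floor) * inhib)
    rows = []
    for rep in range(n_replicates):
        atp = noise.apply(net_true + background_signal, rng)
        amp = noise.apply(np.full_like(conc, background_signal), rng)
        for c, a, b in zip(conc, atp, amp):
            rows.append(
                {"conc_um": c, "atp_flag": True, "signal": a, "replicate": rep}
            )
            rows.append(
                {"conc_um": c, "atp_flag": False, "signal": b, "replicate": rep}
            )
    truth = {
        "ic50_um": true_ic50_um,
        "hill": true_hill,
        "max_inhibition_pct": max_inhibition_pct,
        "top_signal": top_signal,
        "background_signal": background_signal,
    }
    return VesiclePlate(pd.DataFrame(rows)), truth


def dataclasses_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)
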