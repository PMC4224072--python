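"""Membrane vesicle transport-inhibition assay analysis.

BSEP-expressing inside-out vesicles take up a radiolabelled probe substrate
(taurocholate, 2 µM) only in the presence of ATP; wells run with AMP instead
measure passive diffusion background. The ATP-dependent (net) signal across
an inhibitor serial dilution is fitted with a four-parameter logistic to an
IC50, which — following the convention used when the inhibition mode is
undetermined — is carried forward as the Ki.

Nominal stock-well concentrations are converted to in-well concentrations by
the documented incubation dilution (0.75 µl of inhibitor solution into a
75 µl incubation: a factor of 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

INCUBATION_DILUTION = 0.01  # 1% of the final incubation volume

# nominal serial dilution of the documented protocol (µM, stock-well)
DEFAULT_SERIAL_DILUTION_UM = (
    30000.0, 10000.0, 3160.0, 1000.0, 316.0, 100.0, 31.6, 10.0,
)


@dataclass
class VesiclePlate:
    """Long-format vesicle plate: one row per well."""

    data: pd.DataFrame  # columns: conc_um, atp_flag (bool), signal, replicate

    def __post_init__(self) -> None:
        required = {"conc_um", "atp_flag", "signal", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate missing columns {sorted(missing)}")
        if (self.data["signal"] < 0).any():
            raise ValueError("signals must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "VesiclePlate":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["conc_um"].unique())[::-1]


def atp_dependent_uptake(plate: VesiclePlate) -> pd.DataFrame:
    """Net transporter-mediated signal per concentration.

    net = mean(+ATP wells) − mean(AMP background wells), floored at zero.
    Raises if any concentration lacks matched ±ATP wells.
    """
    df = plate.data
    out = []
    for conc, sub in df.groupby("conc_um"):
        atp = sub[sub["atp_flag"]]["signal"]
        amp = sub[~sub["atp_flag"]]["signal"]
        if len(atp) == 0 or len(amp) == 0:
            raise ValueError(f"unmatched ±ATP wells at {conc} µM")
        out.append(
            {
                "conc_um": float(conc),
                "net_signal": max(float(atp.mean() - amp.mean()), 0.0),
                "n_replicates": int(min(len(atp), len(amp))),
            }
        )
    return pd.DataFrame(out).sort_values("conc_um", ignore_index=True)


@dataclass
class IC50Result:
    ic50_um: float
    hill: float
    max_inhibition_pct: float
    top: float
    bottom: float
    ic50_ci_um: tuple
    success: bool
    message: str = ""
    provenance: str = ""


def _logistic(c, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(
    conc_um: np.ndarray,
    net_signal: np.ndarray,
    in_well: bool = False,
) -> IC50Result:
    """Four-parameter logistic fit of net uptake vs inhibitor concentration.

    Concentrations are log-spaced serial dilutions; the bottom plateau is
    bounded at >= 0. ``in_well=True`` converts nominal stock concentrations
    to in-well values before fitting (the reported IC50 then refers to
    in-well exposure). A dataset with no transition inside the tested range
    returns ``success=False``.
    """
    conc = np.asarray(conc_um, dtype=float)
    sig = np.asarray(net_signal, dtype=float)
    if len(conc) < 5:
        raise ValueError("need >= 5 concentrations spanning the transition")
    if in_well:
        conc = conc * INCUBATION_DILUTION
    top0 = float(sig.max())
    bot0 = float(max(sig.min(), 0.0))
    # no-transition guard: the spread must exceed plate noise scale
    if top0 - bot0 < 0.05 * max(top0, 1e-12):
        return IC50Result(
            ic50_um=np.nan, hill=np.nan, max_inhibition_pct=0.0, top=top0,
            bottom=bot0, ic50_ci_um=(np.nan, np.nan), success=False,
            message="no inhibition transition in the tested range",
        )
    ic50_0 = float(np.sqrt(conc.min() * conc.max()))
    try:
        popt, pcov = curve_fit(
            _logistic,
            conc,
            sig,
            p0=[top0, bot0, ic50_0, 1.0],
            bounds=([0.0, 0.0, conc.min() / 1e3, 0.2],
                    [10 * top0 + 1e-9, top0 + 1e-9, conc.max() * 1e3, 8.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return IC50Result(
            ic50_um=np.nan, hill=np.nan, max_inhibition_pct=np.nan, top=top0,
            bottom=bot0, ic50_ci_um=(np.nan, np.nan), success=False,
            message=str(exc),
        )
    top, bottom, ic50, hill = popt
    se = float(np.sqrt(np.abs(pcov[2, 2])))
    max_inh = 100.0 * (1.0 - bottom / top) if top > 0 else np.nan
    inside = conc.min() / 10 <= ic50 <= conc.max() * 10
    return IC50Result(
        ic50_um=float(ic50),
        hill=float(hill),
        max_inhibition_pct=float(max_inh),
        top=float(top),
        bottom=float(bottom),
        ic50_ci_um=(float(ic50 - 1.96 * se), float(ic50 + 1.96 * se)),
        success=bool(inside),
        message="" if inside else "fitted IC50 outside the tested range",
    )


def fit_plate_ic50(plate: VesiclePlate, in_well: bool = False) -> IC50Result:
    net = atp_dependent_uptake(plate)
    return fit_ic50(net["conc_um"].to_numpy(), net["net_signal"].to_numpy(), in_well)


def ki_from_ic50(ic50_um: float) -> dict:
    """Ki approximated by the IC50 (convention when the mode is undetermined).

    Returns the value with an attached provenance note so downstream tables
    can flag the approximation.
    """
    if not ic50_um > 0:
        raise ValueError("ic50 must be > 0")
    return {
        "ki_um": float(ic50_um),
        "provenance": "Ki approximated by IC50; inhibition mode undetermined",
    }
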