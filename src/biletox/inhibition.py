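"""Competitive / noncompetitive inhibition kinetics.

These are the scalar reference implementations of the inhibition algebra used
throughout the simulator; the compiled ODE kernel applies the same rules.
Multiple inhibitors acting on one transporter combine multiplicatively in
their (1 + I/Ki) factors.
"""

from __future__ import annotations

from .compounds import InhibitionSpec


def apply_inhibition(
    vmax: float,
    km: float,
    inhibitor_conc_um: float,
    spec: InhibitionSpec,
) -> tuple:
    """Apparent (vmax, km) of a Michaelis-Menten transporter under one inhibitor.

    Competitive: km_app = km * (1 + I/Ki), vmax unchanged.
    Noncompetitive: vmax_app = vmax / (1 + I/Ki), km unchanged.
    """
    if inhibitor_conc_um < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    factor = 1.0 + inhibitor_conc_um / spec.ki_um
    if spec.mode == "competitive":
        return vmax, km * factor
    return vmax / factor, km


def combined_factors(pairs) -> tuple:
    """Multiplicative (competitive, noncompetitive) factors for one transporter.

    ``pairs`` is an iterable of (inhibitor_conc_um, InhibitionSpec); returns
    (f_comp, f_noncomp) such that km_app = km * f_comp and
    vmax_app = vmax / f_noncomp.
    """
    f_c = 1.0
    f_n = 1.0
    for conc, spec in pairs:
        if conc < 0:
            raise ValueError("inhibitor concentration must be >= 0")
        f = 1.0 + conc / spec.ki_um
        if spec.mode == "competitive":
            f_c *= f
        else:
            f_n *= f
    return f_c, f_n


def etc_inhibition_factor(inhibitor_conc_um, ki_etc_um) -> float:
    """Fractional ATP synthesis capacity under electron-transport-chain inhibitors.

    factor = prod_j 1 / (1 + I_j / Ki_j), in (0, 1]; equals 1 with no
    inhibitors present.
    """
    factor = 1.0
    for conc, ki in zip(inhibitor_conc_um, ki_etc_um):
        if conc < 0:
            raise ValueError("inhibitor concentration must be >= 0")
        if ki is None or ki <= 0:
            continue
        factor *= 1.0 / (1.0 + conc / ki)
    return factor
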