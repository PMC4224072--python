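"""Drug parameterization: PK structure, dosing regimens, transporter inhibition.

A :class:`CompoundModel` holds everything the PBPK layer needs to simulate a
drug and its metabolites, plus the inhibition constants (Ki) that couple drug
exposure to the bile acid and mitochondrial submodels. Parameters carry their
units in the field names; clearances and uptake capacities that scale
allometrically are expressed per kg^0.75 of bodyweight.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

TRANSPORTERS = ("BSEP", "NTCP", "BASOLATERAL", "ETC")
INHIBITION_MODES = ("competitive", "noncompetitive")


@dataclass
class InhibitionSpec:
    """One transporter inhibited by one chemical species.

    ``mode`` follows classical enzyme kinetics: competitive inhibition scales
    the apparent Km by (1 + I/Ki); noncompetitive inhibition scales the
    apparent Vmax by 1/(1 + I/Ki). ETC (electron transport chain) inhibition
    is always treated as a Vmax-type (noncompetitive) effect on ATP synthesis
    capacity.
    """

    transporter: str
    ki_um: float
    mode: str = "noncompetitive"

    def __post_init__(self) -> None:
        if self.transporter not in TRANSPORTERS:
            raise ValueError(f"unknown transporter {self.transporter!r}")
        if self.mode not in INHIBITION_MODES:
            raise ValueError(f"unknown inhibition mode {self.mode!r}")
        if not self.ki_um > 0:
            raise ValueError("ki_um must be > 0")


@dataclass
class InductionSpec:
    """First-order autoinduction of hepatic uptake and/or metabolism.

    The induction multiplier E(t) rises from 1 toward ``fold_max`` with rate
    ``k_ind_per_h`` and multiplies the targeted Vmax values.
    """

    targets: tuple = ("uptake_vmax", "metabolism_vmax")
    fold_max: float = 1.0
    k_ind_per_h: float = 0.01

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        for t in self.targets:
            if t not in ("uptake_vmax", "metabolism_vmax"):
                raise ValueError(f"unknown induction target {t!r}")
        if self.fold_max < 1:
            raise ValueError("fold_max must be >= 1")
        if not self.k_ind_per_h > 0:
            raise ValueError("k_ind_per_h must be > 0")


@dataclass
class MetabolitePath:
    """Saturable hepatic formation of one metabolite from the parent drug.

    The product lives in a liver compartment, exchanges with a central
    (plasma) compartment, and is eliminated by biliary and optional renal
    clearance.
    """

    product_name: str
    vmax_formation_umol_per_h: float
    km_formation_um: float
    product_biliary_cl_ml_per_h_kg075: float
    product_inhibitions: list = field(default_factory=list)
    product_efflux_cl_l_per_h: float = 5.0
    product_v_central_l_per_kg: float = 0.2
    product_renal_cl_l_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax_formation_umol_per_h < 0:
            raise ValueError("vmax_formation must be >= 0")
        if not self.km_formation_um > 0:
            raise ValueError("km_formation must be > 0")
        self.product_inhibitions = [
            i if isinstance(i, InhibitionSpec) else InhibitionSpec(**i)
            for i in self.product_inhibitions
        ]


@dataclass
class CompoundModel:
    """Full PK + inhibition parameterization of one drug."""

    name: str
    molecular_weight_g_per_mol: float
    ka_per_h: float
    f_abs: float
    uptake_vmax_umol_per_h_kg075: float
    uptake_km_um: float
    passive_cl_l_per_h: float
    biliary_cl_ml_per_h_kg075: float
    renal_cl_l_per_h: float
    v_central_l_per_kg: float
    v_peripheral_l_per_kg: float
    q_peripheral_l_per_h: float
    metabolites: list = field(default_factory=list)
    induction: InductionSpec | None = None
    inhibitions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for fname in (
            "molecular_weight_g_per_mol",
            "ka_per_h",
            "uptake_vmax_umol_per_h_kg075",
            "uptake_km_um",
            "passive_cl_l_per_h",
            "biliary_cl_ml_per_h_kg075",
            "renal_cl_l_per_h",
            "v_central_l_per_kg",
            "v_peripheral_l_per_kg",
            "q_peripheral_l_per_h",
        ):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")
        if not 0 <= self.f_abs <= 1:
            raise ValueError("f_abs must be in [0, 1]")
        self.metabolites = [
            m if isinstance(m, MetabolitePath) else MetabolitePath(**m)
            for m in self.metabolites
        ]
        self.inhibitions = [
            i if isinstance(i, InhibitionSpec) else InhibitionSpec(**i)
            for i in self.inhibitions
        ]
        if self.induction is not None and not isinstance(self.induction, InductionSpec):
            self.induction = InductionSpec(**self.induction)

    # -- convenience -------------------------------------------------------
    def copy(self) -> "CompoundModel":
        return copy.deepcopy(self)

    def species_names(self) -> list:
        """Parent followed by metabolite product names."""
        return [self.name] + [m.product_name for m in self.metabolites]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CompoundModel":
        return cls(**d)


@dataclass
class DoseRegimen:
    """Repeated-dose schedule. ``per_kg`` interprets amount as mg/kg (rat)."""

    amount_mg: float
    interval_h: float
    n_doses: int
    route: str = "oral"
    per_kg: bool = False

    def __post_init__(self) -> None:
        if self.amount_mg < 0:
            raise ValueError("amount_mg must be >= 0")
        if not self.interval_h > 0:
            raise ValueError("interval_h must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.route not in ("oral", "iv"):
            raise ValueError("route must be 'oral' or 'iv'")

    @property
    def dose_times_h(self):
        return [i * self.interval_h for i in range(self.n_doses)]

    @property
    def duration_h(self) -> float:
        return self.n_doses * self.interval_h

    def dose_umol(self, compound: CompoundModel, bodyweight_kg: float) -> float:
        mg = self.amount_mg * (bodyweight_kg if self.per_kg else 1.0)
        return mg / compound.molecular_weight_g_per_mol * 1000.0


def apply_impaired_metabolism(compound: CompoundModel, factor: float) -> CompoundModel:
    """Return a copy with every metabolite formation Vmax scaled by ``factor``.

    Models an impaired-metabolizer phenotype (e.g. a CYP polymorphism): only
    the metabolic capacity changes; uptake, clearances and inhibition
    constants are untouched.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    out = compound.copy()
    for m in out.metabolites:
        m.vmax_formation_umol_per_h *= factor
    return out


# -- config I/O ------------------------------------------------------------

def _bundled(name: str):
    return resources.files("biletox.data").joinpath(f"{name}.yaml")


def load_compound(name_or_path: str) -> CompoundModel:
    """Load a compound from a YAML file or from the bundled parameter sets."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        text = _bundled(str(name_or_path)).read_text()
    d = yaml.safe_load(text)
    d.pop("notes", None)
    return CompoundModel.from_dict(d)


def save_compound(compound: CompoundModel, path: str) -> None:
    Path(path).write_text(yaml.safe_dump(compound.to_dict(), sort_keys=False))
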