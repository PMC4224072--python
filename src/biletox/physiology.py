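"""Species physiology: volumes, flows, bile acid turnover and meal schedule.

The human and rat parameter sets live in ``biletox/data/human.yaml`` and
``rat.yaml`` together with the bile acid transporter capacities. The defaults
were calibrated (see docs/methods.md) so that the drug-free human holds
hepatic ATP at 4.2 mM and the rat at 2.0 mM, and so that the rat's toxic
(CDCA/LCA-class) liver bile acid exposure sits well below the human's — the
rat synthesizes proportionally less CDCA and, unlike the human, clears LCA by
hydroxylation to hyodeoxycholic acid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .bile_acid import TransporterParams


@dataclass
class SpeciesPhysiology:
    species: str  # "human" | "rat"
    bodyweight_kg: float
    liver_volume_l: float
    blood_volume_l: float
    portal_volume_l: float
    q_portal_l_per_h: float
    q_hepatic_artery_l_per_h: float
    ba_synthesis_rate_umol_per_h: float  # hepatic CDCA synthesis
    toxic_pool_fraction: float  # share of the total BA pool that is CDCA/LCA-class
    lca_hydroxylation_cl_l_per_h: float  # 0 in human
    gut_conversion_k_per_h: float  # CDCA -> LCA by gut flora
    conjugation_k_per_h: float  # hepatic amidation
    sulfation_k_per_h: float  # hepatic LCA sulfation
    gut_transit_k_per_h: float  # first-order exit from gut lumen
    fecal_loss_fraction: float  # share of gut outflow lost in feces (CDCA-class)
    lca_fecal_loss_fraction: float  # LCA-class share (poorly reabsorbed)
    gallbladder_empty_fraction: float
    meal_times_h: list = field(default_factory=lambda: [0.0, 8.0, 16.0])
    baseline_atp_mm: float = 4.2

    def __post_init__(self) -> None:
        if self.species not in ("human", "rat"):
            raise ValueError("species must be 'human' or 'rat'")
        for f in (
            "toxic_pool_fraction",
            "fecal_loss_fraction",
            "lca_fecal_loss_fraction",
            "gallbladder_empty_fraction",
        ):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.species == "human" and self.lca_hydroxylation_cl_l_per_h != 0:
            raise ValueError("LCA hydroxylation does not occur in the human")

    @property
    def allometric_kg075(self) -> float:
        return self.bodyweight_kg ** 0.75

    def meal_schedule(self, duration_h: float):
        """Absolute meal times (h) over a simulation of the given length."""
        times = []
        day = 0
        while day * 24.0 < duration_h:
            for m in self.meal_times_h:
                t = day * 24.0 + m
                if 0 < t < duration_h:
                    times.append(t)
            day += 1
        return sorted(times)

    def copy(self) -> "SpeciesPhysiology":
        return dataclasses.replace(
            self, meal_times_h=list(self.meal_times_h)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _bundled_text(name: str) -> str:
    return resources.files("biletox.data").joinpath(f"{name}.yaml").read_text()


def load_physiology(name_or_path: str):
    """Load (SpeciesPhysiology, TransporterParams) from YAML.

    ``name_or_path`` is either a path to a YAML file or one of the bundled
    names ("human", "rat").
    """
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        text = _bundled_text(str(name_or_path))
    d = yaml.safe_load(text)
    d.pop("notes", None)
    tr = d.pop("transporters")
    phys = SpeciesPhysiology(**d)
    transporters = TransporterParams(
        vmax_umol_per_h=tr["vmax_umol_per_h"], km_um=tr["km_um"]
    )
    return phys, transporters


def save_physiology(phys: SpeciesPhysiology, transporters: TransporterParams, path) -> None:
    d = phys.to_dict()
    d["transporters"] = {
        "vmax_umol_per_h": {
            k: {s: float(x) for s, x in zip(_species(), v)}
            for k, v in transporters.vmax_umol_per_h.items()
        },
        "km_um": {
            k: {s: float(x) for s, x in zip(_species(), v)}
            for k, v in transporters.km_um.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _species():
    from .bile_acid import BA_SPECIES

    return BA_SPECIES
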