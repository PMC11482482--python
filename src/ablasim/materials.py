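"""Material constants for microwave-ablation simulations.

Houses the per-material electromagnetic and thermal constants used by the
EM and bioheat solvers: relative permittivity and electric conductivity at
the operating frequency, density, specific heat, thermal conductivity,
blood-perfusion rate and metabolic heat.  Two case kinds are supported:

``phantom``
    A tissue-mimicking polyacrylamide gel column.  Perfusion and metabolic
    heat are switched off (``omega_b = Qm = 0``); dielectric and thermal
    constants default to the liver values.
``clinical``
    Perfused liver with an embedded tumor; liver and tumor carry metabolic
    heat and the blood perfusion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "MaterialProperties",
    "BloodProperties",
    "MaterialTable",
    "build_material_table",
    "delivered_power",
    "NEEDLE_MATERIALS",
]

#: material names that belong to the applicator (excluded from the tissue solve)
NEEDLE_MATERIALS = frozenset(
    {"inner_conductor", "outer_conductor", "dielectric", "catheter", "tip", "water"}
)


@dataclass(frozen=True)
class MaterialProperties:
    """EM + thermal constants of a single material.

    Parameters
    ----------
    relative_permittivity : float
        Real relative permittivity at the operating frequency (>= 1).
    electric_conductivity : float
        Effective conductivity in S/m (>= 0); drives dielectric heating.
    relative_permeability : float
        Relative permeability (1 for all materials here).
    density, specific_heat, thermal_conductivity :
        rho (kg/m^3), Cp (J/(kg K)), k (W/(m K)).  ``thermal_conductivity``
        may be zero: the perfusion-relaxation oracle suppresses conduction
        through exactly this hook.
    perfusion_rate : float
        Blood perfusion rate omega_b (1/s) applying inside this material.
    metabolic_heat : float
        Volumetric metabolic source Qm (W/m^3).
    perfect_conductor : bool
        Treat as PEC in the EM solve (copper conductors).
    """

    name: str
    relative_permittivity: float
    electric_conductivity: float
    density: float
    specific_heat: float
    thermal_conductivity: float
    relative_permeability: float = 1.0
    perfusion_rate: float = 0.0
    metabolic_heat: float = 0.0
    perfect_conductor: bool = False

    def __post_init__(self) -> None:
        if self.relative_permittivity < 1.0:
            raise ValueError(f"{self.name}: relative permittivity must be >= 1")
        if self.electric_conductivity < 0.0:
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if self.density <= 0.0 or self.specific_heat <= 0.0:
            raise ValueError(f"{self.name}: density and specific heat must be > 0")
        if self.thermal_conductivity < 0.0:
            raise ValueError(f"{self.name}: thermal conductivity must be >= 0")
        if self.perfusion_rate < 0.0 or self.metabolic_heat < 0.0:
            raise ValueError(f"{self.name}: perfusion and metabolic heat must be >= 0")


@dataclass(frozen=True)
class BloodProperties:
    """Blood constants entering the Pennes perfusion term rho_b*Cb*omega_b*(Tb-T)."""

    density: float = 1000.0  # kg/m^3
    specific_heat: float = 3639.0  # J/(kg K)
    perfusion_rate: float = 0.00361  # 1/s
    temperature: float = 310.15  # K

    def __post_init__(self) -> None:
        if min(self.density, self.specific_heat, self.perfusion_rate, self.temperature) <= 0:
            raise ValueError("blood properties must be strictly positive")
        if not (273.0 <= self.temperature <= 320.0):
            raise ValueError("blood temperature outside physiological range [273, 320] K")


@dataclass(frozen=True)
class MaterialTable:
    """All materials of one case plus the blood constants."""

    case_kind: str
    materials: Mapping[str, MaterialProperties]
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __getitem__(self, name: str) -> MaterialProperties:
        return self.materials[name]

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    @property
    def tissue_name(self) -> str:
        """Name of the background medium (phantom gel or liver)."""
        return "phantom" if self.case_kind == "phantom" else "liver"

    def to_dict(self) -> dict:
        """Plain-dict form for config serialization (round-trips exactly)."""
        out: dict = {"case_kind": self.case_kind, "blood": vars(self.blood).copy(), "materials": {}}
        for name, m in self.materials.items():
            d = {k: v for k, v in vars(m).items() if k != "name"}
            out["materials"][name] = d
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialTable":
        mats = {
            name: MaterialProperties(name=name, **props) for name, props in d["materials"].items()
        }
        return cls(case_kind=d["case_kind"], materials=mats, blood=BloodProperties(**d["blood"]))


# Liver / tumor / blood constants at 2.45 GHz; phantom medium mimics liver with
# perfusion and metabolism switched off.  Applicator-material thermal constants
# are nominal handbook values (the applicator interior is replaced by the
# coolant boundary condition in the thermal solve, so they never enter results).
_TISSUE = {
    "liver": dict(
        relative_permittivity=43.03,
        electric_conductivity=1.69,
        density=1069.0,
        specific_heat=3600.0,
        thermal_conductivity=0.55,
        metabolic_heat=1000.0,
    ),
    "tumor": dict(
        relative_permittivity=54.8,
        electric_conductivity=2.0,
        density=1040.0,
        specific_heat=3760.0,
        thermal_conductivity=0.57,
        metabolic_heat=1300.0,
    ),
}

_APPLICATOR = {
    "inner_conductor": dict(
        relative_permittivity=1.0,
        electric_conductivity=0.0,
        density=8960.0,
        specific_heat=385.0,
        thermal_conductivity=400.0,
        perfect_conductor=True,
    ),
    "outer_conductor": dict(
        relative_permittivity=1.0,
        electric_conductivity=0.0,
        density=8960.0,
        specific_heat=385.0,
        thermal_conductivity=400.0,
        perfect_conductor=True,
    ),
    "dielectric": dict(  # PTFE coax filling
        relative_permittivity=2.03,
        electric_conductivity=0.0,
        density=2200.0,
        specific_heat=1050.0,
        thermal_conductivity=0.25,
    ),
    "catheter": dict(
        relative_permittivity=2.6,
        electric_conductivity=0.0,
        density=1400.0,
        specific_heat=1200.0,
        thermal_conductivity=0.30,
    ),
    "tip": dict(  # ceramic tip; permittivity not published, alumina-like default
        relative_permittivity=9.0,
        electric_conductivity=0.0,
        density=3900.0,
        specific_heat=880.0,
        thermal_conductivity=30.0,
    ),
    "water": dict(  # coolant circulating in the shaft
        relative_permittivity=77.0,
        electric_conductivity=0.0,
        density=998.0,
        specific_heat=4182.0,
        thermal_conductivity=0.6,
    ),
}

# Override keys follow the config-file naming: <symbol>_<material>, e.g.
# sigma_liver, eps_tumor, k_liver, Qm_tumor, rho_blood, Cp_blood, omega_blood.
_FIELD_BY_SYMBOL = {
    "eps": "relative_permittivity",
    "sigma": "electric_conductivity",
    "mu": "relative_permeability",
    "rho": "density",
    "Cp": "specific_heat",
    "k": "thermal_conductivity",
    "omega": "perfusion_rate",
    "Qm": "metabolic_heat",
}


def _apply_override(materials: dict, blood: BloodProperties, key: str, value: float):
    try:
        symbol, target = key.split("_", 1)
        fieldname = _FIELD_BY_SYMBOL[symbol]
    except (ValueError, KeyError):
        raise KeyError(f"unknown override key {key!r}") from None
    if target == "blood":
        blood_fields = {"rho": "density", "Cp": "specific_heat", "omega": "perfusion_rate", "T": "temperature"}
        return materials, replace(blood, **{blood_fields[symbol]: float(value)})
    if target not in materials:
        raise KeyError(f"override {key!r} names unknown material {target!r}")
    materials[target] = replace(materials[target], **{fieldname: float(value)})
    return materials, blood


def build_material_table(case_kind: str, overrides: Mapping[str, float] | None = None) -> MaterialTable:
    """Assemble the material table for a phantom or clinical case.

    The phantom medium uses the liver dielectric/thermal constants with the
    perfusion and metabolic terms zeroed; the clinical case carries perfused
    liver and tumor.  ``overrides`` uses ``<symbol>_<material>`` keys
    (``sigma_liver``, ``Cp_tumor``, ``T_blood`` ...).

    Raises
    ------
    KeyError
        If an override names an unknown material or field.
    ValueError
        If ``case_kind`` is not ``"phantom"`` or ``"clinical"``.
    """
    if case_kind not in ("phantom", "clinical"):
        raise ValueError(f"case_kind must be 'phantom' or 'clinical', got {case_kind!r}")

    blood = BloodProperties()
    materials: dict[str, MaterialProperties] = {}
    if case_kind == "phantom":
        materials["phantom"] = MaterialProperties(
            name="phantom",
            **{**_TISSUE["liver"], "metabolic_heat": 0.0, "perfusion_rate": 0.0},
        )
    else:
        materials["liver"] = MaterialProperties(
            name="liver", **{**_TISSUE["liver"], "perfusion_rate": blood.perfusion_rate}
        )
        materials["tumor"] = MaterialProperties(
            name="tumor", **{**_TISSUE["tumor"], "perfusion_rate": blood.perfusion_rate}
        )
    for name, props in _APPLICATOR.items():
        materials[name] = MaterialProperties(name=name, **props)

    for key, value in (overrides or {}).items():
        materials, blood = _apply_override(materials, blood, key, value)
        # keep tissue perfusion synced to an overridden blood perfusion rate
        if key == "omega_blood" and case_kind == "clinical":
            for t in ("liver", "tumor"):
                materials[t] = replace(materials[t], perfusion_rate=float(value))
    return MaterialTable(case_kind=case_kind, materials=materials, blood=blood)


def delivered_power(generator_power: float, loss_fraction: float) -> float:
    """Power arriving at the applicator after cable losses.

    ``generator_power * (1 - loss_fraction)`` — e.g. a 120 W generator with
    65% cable loss delivers 42 W at the needle.
    """
    if generator_power < 0:
        raise ValueError("generator power must be >= 0")
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss fraction must lie in [0, 1]")
    return generator_power * (1.0 - loss_fraction)
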