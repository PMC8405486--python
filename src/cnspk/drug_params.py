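"""Drug physicochemistry: ionization, partitioning, permeability building blocks.

Ionization follows adapted Henderson-Hasselbalch equations on the strongest
acidic and basic groups; a missing group contributes a neutral fraction of 1.
Non-specific brain binding is represented by diffusion clearances between the
aqueous compartments and the brain cell membrane whose steady-state ratio is
the octanol-water partition coefficient by construction.

The aqueous diffusion and transmembrane permeability relations are
config-parameterized: an inverse-cube-root molecular-weight scaling for free
aqueous diffusion and a log-linear lipophilicity/size relation for bilayer
permeability. Coefficients live in :class:`PermeabilityCoefficients` and
:class:`DiffusionCoefficients` so they can be overridden wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .physiology import PhysiologySet

__all__ = [
    "DrugRecord",
    "IonizationState",
    "MembraneBinding",
    "DiffusionCoefficients",
    "PermeabilityCoefficients",
    "DrugValidationError",
    "compute_phf",
    "octanol_water_partition",
    "aqueous_diffusivity",
    "molecular_radius_nm",
    "transmembrane_permeability",
    "build_membrane_binding",
    "load_drugs",
    "select_kpuu_variant",
]

CHARGE_CLASSES = ("neutral", "acid", "base", "amphoteric")
REGIONS = ("ecf", "lv", "cm")


class DrugValidationError(ValueError):
    """Raised when a drug record violates an invariant."""


@dataclass(frozen=True)
class DrugRecord:
    """Physicochemical and disposition parameters for one compound.

    ``kpuu`` maps region (``ecf``/``lv``/``cm``) to the target unbound
    tissue-to-plasma steady-state ratio. ``kpuu_variants`` optionally holds
    alternative sets (e.g. dose-specific or species-corrected values) keyed
    by label. ``af_reported`` carries externally reported asymmetry factors
    (metadata only; the steady-state solver is the authoritative path).
    """

    name: str
    mw: float
    charge_class: str
    logp: float
    pka: Optional[float] = None
    pkb: Optional[float] = None
    fu_plasma: float = 1.0
    fu_csf: float = 1.0
    kpuu: Mapping[str, float] = field(default_factory=dict)
    kpuu_variants: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    af_reported: Optional[Mapping] = None

    def __post_init__(self) -> None:
        if not (0 < self.mw < 1e5):
            raise DrugValidationError(f"{self.name}: MW must be in (0, 1e5), got {self.mw}")
        if not math.isfinite(self.logp):
            raise DrugValidationError(f"{self.name}: logP must be finite")
        if self.charge_class not in CHARGE_CLASSES:
            raise DrugValidationError(
                f"{self.name}: charge_class must be one of {CHARGE_CLASSES}"
            )
        for label, value in (("fu_plasma", self.fu_plasma), ("fu_csf", self.fu_csf)):
            if not (0 < value <= 1):
                raise DrugValidationError(f"{self.name}: {label} must be in (0, 1], got {value}")
        for region, value in self.kpuu.items():
            if region not in REGIONS:
                raise DrugValidationError(f"{self.name}: unknown Kp_uu region {region!r}")
            if not (value > 0):
                raise DrugValidationError(f"{self.name}: Kp_uu[{region}] must be > 0")


@dataclass(frozen=True)
class IonizationState:
    """Neutral fractions of a drug in one compartment."""

    phf_acidic: float
    phf_basic: float

    @property
    def phf(self) -> float:
        return self.phf_acidic * self.phf_basic


@dataclass(frozen=True)
class MembraneBinding:
    """Diffusion clearances between aqueous phase and brain cell membrane.

    ``cl_wo / cl_ow == p_oct_water`` holds by construction, which makes the
    two-pool steady-state concentration ratio equal to the octanol-water
    partition coefficient.
    """

    p_oct_water: float
    cl_wo: float  # water -> membrane, mL/min
    cl_ow: float  # membrane -> water, mL/min


def compute_phf(drug: DrugRecord, ph_comp: float) -> IonizationState:
    """Neutral drug fraction at a compartment pH.

    PHF_acidic = 1 / (1 + 10^(pH - pKa)); PHF_basic = 1 / (1 + 10^(pKb - pH));
    a missing group contributes 1. The overall PHF is the product.
    """
    if not (1.0 <= ph_comp <= 14.0):
        raise DrugValidationError(f"pH must lie in [1, 14], got {ph_comp}")
    phf_acidic = 1.0 if drug.pka is None else 1.0 / (1.0 + 10.0 ** (ph_comp - drug.pka))
    phf_basic = 1.0 if drug.pkb is None else 1.0 / (1.0 + 10.0 ** (drug.pkb - ph_comp))
    return IonizationState(phf_acidic=phf_acidic, phf_basic=phf_basic)


def octanol_water_partition(logp: float) -> float:
    """P_oct-water = 10^logP."""
    if not math.isfinite(logp):
        raise DrugValidationError(f"logP must be finite, got {logp}")
    return 10.0**logp


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Reference point for the inverse-cube-root aqueous diffusion scaling.

    ``d_ref`` is the free aqueous diffusion coefficient (cm^2/min) at
    molecular weight ``mw_ref`` (g/mol). Default corresponds to ~6e-6 cm^2/s
    for a 100 g/mol solute.
    """

    d_ref: float = 3.6e-4
    mw_ref: float = 100.0


def aqueous_diffusivity(mw: float, coeffs: DiffusionCoefficients | None = None) -> float:
    """Free aqueous diffusion coefficient (cm^2/min), ~ MW^(-1/3)."""
    if not (mw > 0):
        raise DrugValidationError(f"MW must be > 0, got {mw}")
    coeffs = coeffs or DiffusionCoefficients()
    return coeffs.d_ref * (coeffs.mw_ref / mw) ** (1.0 / 3.0)


_AVOGADRO = 6.02214076e23


def molecular_radius_nm(mw: float, density_g_per_ml: float = 1.0) -> float:
    """Effective molecular radius (nm) of a sphere of the given MW and density."""
    if not (mw > 0):
        raise DrugValidationError(f"MW must be > 0, got {mw}")
    radius_cm = (3.0 * mw / (4.0 * math.pi * density_g_per_ml * _AVOGADRO)) ** (1.0 / 3.0)
    return radius_cm * 1e7


@dataclass(frozen=True)
class PermeabilityCoefficients:
    """log10 P_trans (cm/min) = a * logP + b - c * log10(MW)."""

    a: float = 1.0
    b: float = -2.0
    c: float = 1.0


def transmembrane_permeability(
    drug: DrugRecord, coeffs: PermeabilityCoefficients | None = None
) -> float:
    """Phospholipid-bilayer permeability of the neutral species (cm/min)."""
    coeffs = coeffs or PermeabilityCoefficients()
    log_p_trans = coeffs.a * drug.logp + coeffs.b - coeffs.c * math.log10(drug.mw)
    return 10.0**log_p_trans


def build_membrane_binding(
    drug: DrugRecord, physiology: PhysiologySet, kinetic_scale: float | None = None
) -> MembraneBinding:
    """Construct the non-specific binding clearances.

    ``kinetic_scale`` sets CL_wo (water -> membrane, mL/min); CL_ow is
    CL_wo / P_oct-water so the steady-state membrane-to-water concentration
    ratio equals P_oct-water. The default, 50x cerebral blood flow, is large
    relative to barrier clearances so binding is near-equilibrium yet
    time-resolved.
    """
    if kinetic_scale is None:
        kinetic_scale = 50.0 * physiology.q_cbf
    if not (kinetic_scale > 0):
        raise DrugValidationError(f"kinetic_scale must be > 0, got {kinetic_scale}")
    p_ow = octanol_water_partition(drug.logp)
    return MembraneBinding(p_oct_water=p_ow, cl_wo=kinetic_scale, cl_ow=kinetic_scale / p_ow)


# ---------------------------------------------------------------------------
# fixtures


def _record_from_entry(name: str, entry: Mapping) -> DrugRecord:
    return DrugRecord(
        name=name,
        mw=float(entry["mw"]["value"]),
        charge_class=str(entry["charge_class"]),
        pka=None if entry.get("pka") is None else float(entry["pka"]),
        pkb=None if entry.get("pkb") is None else float(entry["pkb"]),
        logp=float(entry["logp"]),
        fu_plasma=float(entry.get("fu_plasma", 1.0)),
        fu_csf=float(entry.get("fu_csf", 1.0)),
        kpuu=dict(entry.get("kpuu", {})),
        kpuu_variants={k: dict(v) for k, v in entry.get("kpuu_variants", {}).items()},
        af_reported=entry.get("af_reported"),
    )


def load_drugs(source: Union[str, Path, Mapping, None] = None) -> dict[str, DrugRecord]:
    """Load drug records; with no argument, the packaged fixture set."""
    if source is None:
        text = resources.files("cnspk.data").joinpath("drugs.yaml").read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as handle:
            doc = yaml.safe_load(handle)
    return {name: _record_from_entry(name, entry) for name, entry in doc.items()}


def select_kpuu_variant(drug: DrugRecord, variant: str) -> DrugRecord:
    """Return a copy of ``drug`` with its Kp_uu targets replaced by a named
    variant set (e.g. a dose-specific or species-corrected set)."""
    if variant not in drug.kpuu_variants:
        raise DrugValidationError(
            f"{drug.name}: unknown Kp_uu variant {variant!r}; "
            f"available: {sorted(drug.kpuu_variants)}"
        )
    return replace(drug, kpuu=dict(drug.kpuu_variants[variant]))
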