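"""CNS physiological parameter sets.

Defines, validates, loads, and perturbs the anatomical/physiological
constants (compartment volumes, fluid flows, barrier surface areas and
geometry, compartment pH) that parameterize the CNS transport model.

Canonical units, repo-wide: volumes in mL, flows in mL/min, surface areas
in cm^2, tight-junction pore radius in nm, paracellular path length in um,
cell radius in um, pH dimensionless. Every numeric field in a config
document must carry a matching units annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

__all__ = [
    "PhysiologySet",
    "Perturbation",
    "ConfigError",
    "PhysiologyValidationError",
    "load_physiology",
    "physiology_to_config",
    "serialize_physiology",
    "derive_sa_bcm",
    "apply_perturbations",
    "CANONICAL_UNITS",
]


class ConfigError(ValueError):
    """Raised when a config document is structurally invalid or incomplete."""


class PhysiologyValidationError(ValueError):
    """Raised when a physiological value violates a model invariant."""


#: field name -> required units annotation in config documents
CANONICAL_UNITS = {
    "v_mv": "mL",
    "v_ecf": "mL",
    "v_icf": "mL",
    "v_lys": "mL",
    "v_bcm": "mL",
    "v_lv": "mL",
    "v_tfv": "mL",
    "v_cm": "mL",
    "v_sas": "mL",
    "v_brain": "mL",
    "q_cbf": "mL/min",
    "q_ecf": "mL/min",
    "q_csf": "mL/min",
    "sa_bbb": "cm^2",
    "sa_bcsfb_lv": "cm^2",
    "sa_bcsfb_tfv": "cm^2",
    "sa_bcm": "cm^2",
    "sa_lys": "cm^2",
    "pore_radius_nm": "nm",
    "para_path_um": "um",
    "para_fraction": "dimensionless",
    "cell_count": "count",
    "cell_radius_um": "um",
    "ph_plasma": "pH",
    "ph_ecf": "pH",
    "ph_icf": "pH",
    "ph_lys": "pH",
    "ph_csf": "pH",
    "bcm_volume_fraction": "dimensionless",
}

_POSITIVE_FIELDS = (
    "v_mv", "v_ecf", "v_icf", "v_lys", "v_bcm", "v_lv", "v_tfv", "v_cm",
    "v_sas", "v_brain", "q_cbf", "q_ecf", "q_csf", "sa_bbb", "sa_bcsfb_lv",
    "sa_bcsfb_tfv", "sa_bcm", "sa_lys", "pore_radius_nm", "para_path_um",
    "cell_count", "cell_radius_um", "bcm_volume_fraction",
)
_PH_FIELDS = ("ph_plasma", "ph_ecf", "ph_icf", "ph_lys", "ph_csf")

#: fields that may be absent from a config because they are derived
_DERIVABLE = ("v_bcm", "sa_bcm")


@dataclass(frozen=True)
class PhysiologySet:
    """All physiological constants for one species/population.

    ``v_bcm`` is the brain-cell-membrane (phospholipid) compartment volume,
    5% of total brain volume when derived from defaults; ``sa_bcm`` is the
    total brain-cell membrane area, derived from cell count and radius
    (equal spheres) when not given explicitly.
    """

    species: str
    # volumes, mL
    v_mv: float
    v_ecf: float
    v_icf: float
    v_lys: float
    v_lv: float
    v_tfv: float
    v_cm: float
    v_sas: float
    v_brain: float
    # flows, mL/min
    q_cbf: float
    q_ecf: float
    q_csf: float
    # surface areas, cm^2
    sa_bbb: float
    sa_bcsfb_lv: float
    sa_bcsfb_tfv: float
    sa_lys: float
    # barrier geometry
    pore_radius_nm: float
    para_path_um: float
    para_fraction: float
    # brain cells, for SA_BCM derivation
    cell_count: float
    cell_radius_um: float
    # pH per compartment
    ph_plasma: float
    ph_ecf: float
    ph_icf: float
    ph_lys: float
    ph_csf: float
    # derived unless overridden
    bcm_volume_fraction: float = 0.05
    v_bcm: float = -1.0
    sa_bcm: float = -1.0

    def __post_init__(self) -> None:
        if self.v_bcm <= 0:
            object.__setattr__(
                self, "v_bcm", self.bcm_volume_fraction * self.v_brain
            )
        if self.sa_bcm <= 0:
            object.__setattr__(
                self, "sa_bcm", derive_sa_bcm(self.cell_count, self.cell_radius_um)
            )
        self._validate()

    def _validate(self) -> None:
        for name in _POSITIVE_FIELDS + ("v_bcm", "sa_bcm"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise PhysiologyValidationError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise PhysiologyValidationError(f"{name} must be strictly positive, got {value}")
        for name in _PH_FIELDS:
            value = getattr(self, name)
            if not (1.0 <= value <= 14.0):
                raise PhysiologyValidationError(f"{name} must lie in [1, 14], got {value}")
        if not (0.0 < self.para_fraction < 1.0):
            raise PhysiologyValidationError(
                f"para_fraction must lie in (0, 1), got {self.para_fraction}"
            )

    def numeric_field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self) if f.name != "species")


@dataclass(frozen=True)
class Perturbation:
    """A multiplicative fold change applied to one physiology field."""

    path: str
    fold: float

    def __post_init__(self) -> None:
        if not (self.fold > 0 and math.isfinite(self.fold)):
            raise PhysiologyValidationError(f"fold change must be > 0, got {self.fold}")


def derive_sa_bcm(cell_count: float, cell_radius_um: float) -> float:
    """Total membrane area (cm^2) of ``cell_count`` equal spheres of radius
    ``cell_radius_um`` (um)."""
    if cell_count < 1:
        raise PhysiologyValidationError(f"cell_count must be >= 1, got {cell_count}")
    if cell_radius_um <= 0:
        raise PhysiologyValidationError(f"cell_radius_um must be > 0, got {cell_radius_um}")
    radius_cm = cell_radius_um * 1e-4
    return cell_count * 4.0 * math.pi * radius_cm**2


def _coerce_document(source: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(source, Mapping):
        return source
    with open(source, "r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"physiology config {source} is not a mapping")
    return doc


def load_physiology(source: Union[str, Path, Mapping], species: str | None = None) -> PhysiologySet:
    """Load and validate a physiology config document.

    The document has a ``species`` label and a ``fields`` mapping in which
    every entry is ``{value: <number>, units: <canonical units string>}``.
    Missing required fields and unit mismatches raise :class:`ConfigError`;
    out-of-range values raise :class:`PhysiologyValidationError`.
    """
    doc = _coerce_document(source)
    doc_species = doc.get("species")
    if doc_species is None:
        raise ConfigError("physiology config is missing the 'species' label")
    if species is not None and doc_species != species:
        raise ConfigError(
            f"requested species {species!r} but config document is for {doc_species!r}"
        )
    raw = doc.get("fields")
    if not isinstance(raw, Mapping):
        raise ConfigError("physiology config is missing the 'fields' mapping")

    values: dict[str, float] = {}
    for name, expected_units in CANONICAL_UNITS.items():
        if name not in raw:
            if name in _DERIVABLE or name == "bcm_volume_fraction":
                continue
            raise ConfigError(f"physiology config is missing required field {name!r}")
        entry = raw[name]
        if not isinstance(entry, Mapping) or "value" not in entry or "units" not in entry:
            raise ConfigError(
                f"field {name!r} must be a mapping with 'value' and 'units' keys"
            )
        if entry["units"] != expected_units:
            raise ConfigError(
                f"field {name!r} has units {entry['units']!r}; expected {expected_units!r}"
            )
        values[name] = float(entry["value"])

    unknown = set(raw) - set(CANONICAL_UNITS)
    if unknown:
        raise ConfigError(f"physiology config has unknown fields: {sorted(unknown)}")
    return PhysiologySet(species=str(doc_species), **values)


def physiology_to_config(physiology: PhysiologySet) -> dict:
    """Serialize to the same document structure :func:`load_physiology` reads."""
    return {
        "species": physiology.species,
        "fields": {
            name: {"value": getattr(physiology, name), "units": units}
            for name, units in CANONICAL_UNITS.items()
        },
    }


def serialize_physiology(physiology: PhysiologySet, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(physiology_to_config(physiology), handle, sort_keys=False)


def apply_perturbations(
    base: PhysiologySet, perturbations: Iterable[Perturbation]
) -> PhysiologySet:
    """Return a new set with each named field multiplied by its fold change.

    ``base`` is unmodified. Derived fields are recomputed when a primitive
    they depend on is perturbed (``v_brain`` -> ``v_bcm``; ``cell_count`` or
    ``cell_radius_um`` -> ``sa_bcm``) unless the derived field itself is
    perturbed directly.
    """
    perturbations = list(perturbations)
    valid = base.numeric_field_names()
    updates: dict[str, float] = {}
    for pert in perturbations:
        if not isinstance(pert, Perturbation):
            pert = Perturbation(*pert)
        if pert.path == "species" or pert.path not in valid:
            raise PhysiologyValidationError(
                f"unknown physiology parameter {pert.path!r}; valid paths: {', '.join(valid)}"
            )
        updates[pert.path] = updates.get(pert.path, getattr(base, pert.path)) * pert.fold

    touched = set(updates)
    if "v_brain" in touched or "bcm_volume_fraction" in touched:
        if "v_bcm" not in touched:
            frac = updates.get("bcm_volume_fraction", base.bcm_volume_fraction)
            updates["v_bcm"] = frac * updates.get("v_brain", base.v_brain)
    if ("cell_count" in touched or "cell_radius_um" in touched) and "sa_bcm" not in touched:
        updates["sa_bcm"] = derive_sa_bcm(
            updates.get("cell_count", base.cell_count),
            updates.get("cell_radius_um", base.cell_radius_um),
        )
    return replace(base, **updates)
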