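"""Minimal unit registry for CMDL quantities.

Every quantity in a record is stored internally in a fixed base unit per
dimension (g, mol, mL, min, mL/min, mol/L, ...), so downstream computations
never re-check units.  The registry is intentionally small: it covers the
units that occur in polymerization records, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Quantity", "UnitError", "parse_quantity", "known_unit", "unit_dimension"]


class UnitError(ValueError):
    """Unknown unit or a unit used with the wrong dimension."""


# unit -> (dimension, factor to base, base unit)
_REGISTRY: dict[str, tuple[str, float, str]] = {
    # mass (base g)
    "g": ("mass", 1.0, "g"),
    "mg": ("mass", 1e-3, "g"),
    "kg": ("mass", 1e3, "g"),
    "ug": ("mass", 1e-6, "g"),
    "µg": ("mass", 1e-6, "g"),
    # amount (base mol)
    "mol": ("amount", 1.0, "mol"),
    "mmol": ("amount", 1e-3, "mol"),
    "umol": ("amount", 1e-6, "mol"),
    "µmol": ("amount", 1e-6, "mol"),
    # volume (base mL)
    "mL": ("volume", 1.0, "mL"),
    "ml": ("volume", 1.0, "mL"),
    "L": ("volume", 1e3, "mL"),
    "l": ("volume", 1e3, "mL"),
    "uL": ("volume", 1e-3, "mL"),
    "µL": ("volume", 1e-3, "mL"),
    "ul": ("volume", 1e-3, "mL"),
    # time (base min)
    "min": ("time", 1.0, "min"),
    "s": ("time", 1.0 / 60.0, "min"),
    "sec": ("time", 1.0 / 60.0, "min"),
    "h": ("time", 60.0, "min"),
    "hr": ("time", 60.0, "min"),
    # volumetric flow (base mL/min)
    "mL/min": ("flow", 1.0, "mL/min"),
    "ml/min": ("flow", 1.0, "mL/min"),
    "uL/min": ("flow", 1e-3, "mL/min"),
    "µL/min": ("flow", 1e-3, "mL/min"),
    "mL/h": ("flow", 1.0 / 60.0, "mL/min"),
    "ml/h": ("flow", 1.0 / 60.0, "mL/min"),
    # molar concentration (base mol/L)
    "mol/L": ("concentration", 1.0, "mol/L"),
    "M": ("concentration", 1.0, "mol/L"),
    "mmol/L": ("concentration", 1e-3, "mol/L"),
    "mM": ("concentration", 1e-3, "mol/L"),
    # mass concentration (base mg/mL)
    "mg/mL": ("mass_concentration", 1.0, "mg/mL"),
    "g/L": ("mass_concentration", 1.0, "mg/mL"),
    # molar mass (base g/mol)
    "g/mol": ("molar_mass", 1.0, "g/mol"),
    "kg/mol": ("molar_mass", 1e3, "g/mol"),
    "Da": ("molar_mass", 1.0, "g/mol"),
    # density (base g/mL)
    "g/mL": ("density", 1.0, "g/mL"),
    "g/ml": ("density", 1.0, "g/mL"),
    # dimensionless
    "%": ("dimensionless", 1e-2, ""),
    "eq": ("dimensionless", 1.0, ""),
    # temperature is recorded but never computed with
    "degC": ("temperature", 1.0, "degC"),
    "K": ("temperature", 1.0, "K"),
}


@dataclass(frozen=True)
class Quantity:
    """A value normalized to the base unit of its dimension."""

    value: float
    unit: str
    dimension: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Quantity({self.value!r} {self.unit or 'dimensionless'})"


def known_unit(unit: str) -> bool:
    return unit in _REGISTRY


def unit_dimension(unit: str) -> str:
    try:
        return _REGISTRY[unit][0]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def parse_quantity(value: float, unit: str) -> Quantity:
    """Normalize ``value unit`` to the base unit of the unit's dimension."""
    try:
        dimension, factor, base = _REGISTRY[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None
    if dimension == "temperature":
        return Quantity(float(value), unit, dimension)
    return Quantity(float(value) * factor, base, dimension)
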