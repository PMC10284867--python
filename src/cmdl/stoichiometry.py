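"""Batch-reaction stoichiometry: moles, equivalents, and concentrations.

Equivalents are mole ratios against a designated reference reagent — by
convention the initiator in a ring-opening polymerization, so the monomer's
equivalents equal the initial monomer-to-initiator ratio [M]0:[I]0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .records import ChemicalEntity

__all__ = [
    "StoichiometryError",
    "ReagentEntry",
    "StoichiometryRow",
    "StoichiometryTable",
    "moles_of",
    "build_table",
    "round_report",
]


class StoichiometryError(ValueError):
    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass
class ReagentEntry:
    """One reagent with exactly one declared quantity form.

    Quantity forms: mass (g), volume (mL, needs density), moles (mol), or a
    solution (volume mL + concentration mol/L).
    """

    entity: ChemicalEntity
    mass_g: Optional[float] = None
    volume_ml: Optional[float] = None
    moles: Optional[float] = None
    solution_volume_ml: Optional[float] = None
    solution_conc_M: Optional[float] = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        forms = [
            self.mass_g is not None,
            self.volume_ml is not None,
            self.moles is not None,
            self.solution_volume_ml is not None,
        ]
        if sum(forms) != 1:
            raise StoichiometryError(
                "AMBIGUOUS_QUANTITY",
                f"reagent {self.entity.name!r} must declare exactly one quantity form",
            )
        if self.solution_volume_ml is not None and self.solution_conc_M is None:
            raise StoichiometryError(
                "MISSING_PROPERTY",
                f"solution reagent {self.entity.name!r} lacks a concentration",
            )

    @property
    def declared_volume_ml(self) -> Optional[float]:
        if self.volume_ml is not None:
            return self.volume_ml
        return self.solution_volume_ml


@dataclass
class StoichiometryRow:
    entity: ChemicalEntity
    moles: float
    equivalents: Optional[float]  # None for solvents (excluded by convention)
    mass_g: Optional[float] = None
    concentration_M: Optional[float] = None


@dataclass
class StoichiometryTable:
    reference_entity: str
    rows: list[StoichiometryRow] = field(default_factory=list)
    total_volume_ml: Optional[float] = None

    def row(self, name: str) -> StoichiometryRow:
        for r in self.rows:
            if r.entity.name == name:
                return r
        raise KeyError(name)

    def equivalents(self, name: str) -> float:
        eq = self.row(name).equivalents
        if eq is None:
            raise StoichiometryError("NO_EQUIVALENTS", f"{name!r} is excluded from equivalents")
        return eq


def moles_of(entry: ReagentEntry) -> float:
    """Convert the entry's declared quantity to moles.

    mass/M, volume*density/M, or solution volume*concentration; the quantity
    must be strictly positive.
    """
    entity = entry.entity
    if entry.moles is not None:
        value = entry.moles
    elif entry.mass_g is not None:
        if entity.molar_mass is None:
            raise StoichiometryError("MISSING_PROPERTY", f"{entity.name!r} lacks a molar mass")
        value = entry.mass_g / entity.molar_mass
    elif entry.volume_ml is not None:
        if entity.density is None:
            raise StoichiometryError("MISSING_PROPERTY", f"{entity.name!r} lacks a density")
        if entity.molar_mass is None:
            raise StoichiometryError("MISSING_PROPERTY", f"{entity.name!r} lacks a molar mass")
        value = entry.volume_ml * entity.density / entity.molar_mass
    else:
        value = entry.solution_volume_ml * entry.solution_conc_M / 1000.0  # mL * mol/L
    if value <= 0:
        raise StoichiometryError(
            "NONPOSITIVE_QUANTITY", f"{entity.name!r} has non-positive amount"
        )
    return value


def build_table(entries: list[ReagentEntry]) -> StoichiometryTable:
    """Tabulate moles, equivalents and concentrations for a batch reaction.

    The reference is the entry flagged ``is_reference``; absent a flag, the
    unique initiator-role entry.  Solvents carry no equivalents but count
    toward the total volume used for concentrations.
    """
    if not entries:
        raise StoichiometryError("EMPTY_REACTION", "no reagents")
    refs = [e for e in entries if e.is_reference]
    if not refs:
        refs = [e for e in entries if e.entity.role == "initiator"]
    if len(refs) != 1:
        raise StoichiometryError(
            "AMBIGUOUS_REFERENCE",
            f"expected exactly one reference reagent, found {len(refs)}",
        )
    reference = refs[0]
    ref_moles = moles_of(reference)

    volumes = [e.declared_volume_ml for e in entries]
    total_volume = sum(v for v in volumes if v is not None) or None

    rows: list[StoichiometryRow] = []
    for entry in entries:
        entity = entry.entity
        n = moles_of(entry)
        solvent = entity.role == "solvent"
        eq: Optional[float]
        if solvent:
            eq = None
        elif entry is reference:
            eq = 1.0  # bit-exact by construction
        else:
            eq = n / ref_moles
        mass = entry.mass_g
        if mass is None and entity.molar_mass is not None:
            mass = n * entity.molar_mass
        conc = None
        if total_volume and not solvent:
            conc = n / (total_volume / 1000.0)
        rows.append(
            StoichiometryRow(
                entity=entity, moles=n, equivalents=eq, mass_g=mass, concentration_M=conc
            )
        )
    return StoichiometryTable(
        reference_entity=reference.entity.name, rows=rows, total_volume_ml=total_volume
    )


def round_report(value: float, *, sigfigs: Optional[int] = None, decimals: Optional[int] = None) -> str:
    """Deterministic half-up rounding for report rendering.

    Internal values are never rounded; this only formats text output.
    """
    if (sigfigs is None) == (decimals is None):
        raise ValueError("specify exactly one of sigfigs= or decimals=")
    d = Decimal(repr(value))
    if decimals is not None:
        q = d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
        return f"{q:.{decimals}f}"
    if d == 0:
        return "0"
    exponent = d.adjusted()  # position of the leading digit
    q = d.quantize(Decimal(1).scaleb(exponent - sigfigs + 1), rounding=ROUND_HALF_UP)
    if q == q.to_integral_value() and q.adjusted() >= sigfigs - 1:
        return str(q.quantize(Decimal(1)))
    return format(q.normalize(), "f")
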