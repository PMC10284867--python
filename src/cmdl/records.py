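"""In-memory model of an interpreted experiment record."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # avoid import cycles; these are only annotations
    from .flow import ReactorGraphSpec, StreamState
    from .polymer import PolymerGraph
    from .stoichiometry import StoichiometryTable

__all__ = [
    "ChemicalEntity",
    "BatchReaction",
    "FlowReaction",
    "ResultMeasurement",
    "ExperimentRecord",
]

ROLES = ("initiator", "monomer", "catalyst", "solvent", "quench", "reagent")
STATES = ("solid", "liquid", "solution")


@dataclass
class ChemicalEntity:
    """A declared chemical: identity, molar mass, physical state, role."""

    name: str
    molar_mass: Optional[float] = None  # g/mol
    smiles: Optional[str] = None
    density: Optional[float] = None  # g/mL
    state: str = "solid"
    role: str = "reagent"

    def __post_init__(self) -> None:
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError(f"{self.name!r}: molar mass must be > 0")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"{self.name!r}: density must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"{self.name!r}: unknown role {self.role!r}")
        if self.state not in STATES:
            raise ValueError(f"{self.name!r}: unknown state {self.state!r}")


@dataclass
class BatchReaction:
    name: str
    table: "StoichiometryTable"
    temperature: Optional[float] = None
    time_min: Optional[float] = None


@dataclass
class FlowReaction:
    name: str
    reactor: str  # name of the reactor graph
    states: dict[str, "StreamState"] = field(default_factory=dict)
    residence_times_min: dict[str, float] = field(default_factory=dict)
    table: Optional["StoichiometryTable"] = None


@dataclass
class ResultMeasurement:
    """A measured outcome tied to a polymer graph.

    ``conversion`` is stored as a fraction (0 = 0%, 1 = 100%); ``dp_assignments``
    maps node paths of the referenced polymer to experimentally assigned DP_n.
    """

    name: str
    polymer: str
    conversion: Optional[float] = None
    mn_gpc: Optional[float] = None  # g/mol
    dispersity: Optional[float] = None
    time_min: Optional[float] = None
    dp_assignments: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conversion is not None and not (0.0 <= self.conversion <= 1.0):
            raise ValueError(f"conversion must be a fraction in [0, 1], got {self.conversion}")
        if self.dispersity is not None and self.dispersity < 1.0:
            raise ValueError(f"dispersity must be >= 1, got {self.dispersity}")
        if self.mn_gpc is not None and self.mn_gpc <= 0:
            raise ValueError(f"M_n must be > 0, got {self.mn_gpc}")


@dataclass
class ExperimentRecord:
    """Fully interpreted record: all computations materialized."""

    chemicals: dict[str, ChemicalEntity] = field(default_factory=dict)
    polymers: dict[str, "PolymerGraph"] = field(default_factory=dict)
    reactors: dict[str, "ReactorGraphSpec"] = field(default_factory=dict)
    reactions: list[BatchReaction | FlowReaction] = field(default_factory=list)
    results: list[ResultMeasurement] = field(default_factory=list)
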