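"""Continuous-flow reactors as directed graphs.

Nodes are physical hardware components (syringe inputs, mixers, tubular
reactor coils, the collection vessel) and directed edges are the tubing
connections, pointing the way the material flows.  Streams are treated as
incompressible and instantaneously mixed, with no reaction consumption
during propagation — the stoichiometry computed is that of the combined
feed, and the residence time of a reactor coil is its volume divided by the
volumetric flow through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .diagnostics import Diagnostic, error
from .records import ChemicalEntity
from .stoichiometry import StoichiometryError, StoichiometryRow, StoichiometryTable

__all__ = [
    "ReactorComponent",
    "ReactorGraphSpec",
    "InputFeed",
    "StreamState",
    "FlowError",
    "validate_reactor_graph",
    "propagate_flows",
    "residence_time",
    "flow_stoichiometry",
    "sankey_export",
]

COMPONENT_KINDS = ("input", "mixer", "reactor", "collection")


class FlowError(ValueError):
    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass(frozen=True)
class ReactorComponent:
    id: str
    kind: str
    volume_ml: Optional[float] = None  # required iff kind == "reactor"

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise FlowError("BAD_KIND", f"component {self.id!r}: unknown kind {self.kind!r}")


@dataclass
class ReactorGraphSpec:
    name: str
    components: list[ReactorComponent] = field(default_factory=list)
    connections: list[tuple[str, str]] = field(default_factory=list)

    def component(self, cid: str) -> ReactorComponent:
        for c in self.components:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(c.id for c in self.components)
        g.add_edges_from(self.connections)
        return g


@dataclass(frozen=True)
class InputFeed:
    """Assignment for one input node: pump rate and feed composition."""

    flow_ml_min: float
    solution: tuple[tuple[str, float], ...] = ()  # (entity name, concentration mol/L)


@dataclass
class StreamState:
    component_id: str
    volumetric_flow_ml_min: float
    molar_flows: dict[str, float] = field(default_factory=dict)  # mol/min

    @property
    def concentrations(self) -> dict[str, float]:
        """mol/L at this point; empty when there is no flow."""
        if self.volumetric_flow_ml_min <= 0:
            return {}
        return {
            k: v / (self.volumetric_flow_ml_min / 1000.0) for k, v in self.molar_flows.items()
        }


def validate_reactor_graph(spec: ReactorGraphSpec) -> list[Diagnostic]:
    """Structural checks: DAG, source/sink roles, reachability, volumes."""
    diags: list[Diagnostic] = []
    g = spec.digraph()
    ids = {c.id for c in spec.components}
    seen: set[tuple[str, str]] = set()
    for a, b in spec.connections:
        for cid in (a, b):
            if cid not in ids:
                diags.append(error("UNRESOLVED_REFERENCE", f"connection names unknown component {cid!r}"))
        if (a, b) in seen:
            diags.append(error("DUPLICATE_CONNECTION", f"connection {a!r} -> {b!r} declared twice"))
        seen.add((a, b))
    if not nx.is_directed_acyclic_graph(g):
        diags.append(error("CYCLE", f"reactor graph {spec.name!r} contains a cycle"))
    inputs = [c for c in spec.components if c.kind == "input"]
    collections = [c for c in spec.components if c.kind == "collection"]
    if not inputs:
        diags.append(error("NO_INPUT", f"reactor graph {spec.name!r} has no input node"))
    if not collections:
        diags.append(error("NO_COLLECTION", f"reactor graph {spec.name!r} has no collection node"))
    for c in inputs:
        if g.in_degree(c.id) > 0:
            diags.append(error("SOURCE_INFLOW", f"input {c.id!r} has incoming connections"))
    for c in collections:
        if g.out_degree(c.id) > 0:
            diags.append(error("SINK_OUTFLOW", f"collection {c.id!r} has outgoing connections"))
    for c in spec.components:
        if c.kind == "reactor" and (c.volume_ml is None or c.volume_ml <= 0):
            diags.append(error("BAD_VOLUME", f"reactor {c.id!r} needs a volume > 0"))
    if inputs and nx.is_directed_acyclic_graph(g):
        reachable: set[str] = set()
        for c in inputs:
            reachable |= {c.id} | nx.descendants(g, c.id)
        for c in spec.components:
            if c.id not in reachable:
                diags.append(error("UNREACHABLE", f"component {c.id!r} is fed by no input"))
    return diags


def propagate_flows(
    spec: ReactorGraphSpec, assignment: dict[str, InputFeed]
) -> dict[str, StreamState]:
    """Propagate volumetric and molar flows through the graph.

    Processes components in topological order; at every non-input node the
    volumetric flow and each entity's molar flow are the sums over incoming
    connections (conservation).  A node with several outgoing connections
    splits its stream equally among them.
    """
    g = spec.digraph()
    inputs = {c.id for c in spec.components if c.kind == "input"}
    missing = inputs - set(assignment)
    if missing:
        raise FlowError("INCOMPLETE_ASSIGNMENT", f"inputs without feeds: {sorted(missing)}")
    extra = set(assignment) - inputs
    if extra:
        raise FlowError("BAD_ASSIGNMENT", f"feeds assigned to non-inputs: {sorted(extra)}")

    states: dict[str, StreamState] = {}
    # flow carried by each connection, filled as sources are processed
    edge_flow: dict[tuple[str, str], float] = {}
    edge_molar: dict[tuple[str, str], dict[str, float]] = {}

    for cid in nx.topological_sort(g):
        if cid in inputs:
            feed = assignment[cid]
            if feed.flow_ml_min < 0:
                raise FlowError("BAD_ASSIGNMENT", f"negative flow at input {cid!r}")
            vol = feed.flow_ml_min
            molar = {
                name: conc * feed.flow_ml_min / 1000.0 for name, conc in feed.solution
            }  # mol/L * mL/min -> mol/min
        else:
            vol = sum(edge_flow.get((p, cid), 0.0) for p in g.predecessors(cid))
            molar = {}
            for p in g.predecessors(cid):
                for name, mf in edge_molar.get((p, cid), {}).items():
                    molar[name] = molar.get(name, 0.0) + mf
        states[cid] = StreamState(component_id=cid, volumetric_flow_ml_min=vol, molar_flows=molar)
        succs = list(g.successors(cid))
        if succs:
            share = 1.0 / len(succs)
            for s in succs:
                edge_flow[(cid, s)] = vol * share
                edge_molar[(cid, s)] = {k: v * share for k, v in molar.items()}
    return states


def residence_time(
    spec: ReactorGraphSpec, states: dict[str, StreamState], reactor_id: str
) -> float:
    """Mean residence time of a reactor coil, min = volume / volumetric flow."""
    component = spec.component(reactor_id)
    if component.kind != "reactor":
        raise FlowError("NOT_A_REACTOR", f"{reactor_id!r} is a {component.kind}")
    flow = states[reactor_id].volumetric_flow_ml_min
    if flow <= 0:
        raise FlowError("ZERO_FLOW", f"no flow through reactor {reactor_id!r}")
    return component.volume_ml / flow


def flow_stoichiometry(
    states: dict[str, StreamState],
    component_id: str,
    reference_entity: str,
    entities: Optional[dict[str, ChemicalEntity]] = None,
) -> StoichiometryTable:
    """Equivalents from molar-flow ratios at one point in the reactor graph."""
    state = states[component_id]
    ref_flow = state.molar_flows.get(reference_entity, 0.0)
    if ref_flow <= 0:
        raise StoichiometryError(
            "MISSING_REFERENCE",
            f"{reference_entity!r} has no molar flow at {component_id!r}",
        )
    conc = state.concentrations
    rows = []
    for name in sorted(state.molar_flows):
        flow = state.molar_flows[name]
        entity = (entities or {}).get(name, ChemicalEntity(name=name))
        rows.append(
            StoichiometryRow(
                entity=entity,
                moles=flow,  # mol/min basis
                equivalents=1.0 if name == reference_entity else flow / ref_flow,
                concentration_M=conc.get(name),
            )
        )
    return StoichiometryTable(reference_entity=reference_entity, rows=rows)


def sankey_export(spec: ReactorGraphSpec, states: dict[str, StreamState]) -> dict:
    """Node/link table for a Sankey rendering of the propagated flows.

    Link values carry the volumetric flow over each connection, so the values
    entering any node sum to that node's volumetric flow.
    """
    g = spec.digraph()
    links = []
    for a, b in spec.connections:
        out_degree = g.out_degree(a)
        value = states[a].volumetric_flow_ml_min / out_degree if out_degree else 0.0
        links.append({"source": a, "target": b, "value": value})
    return {"nodes": [{"id": c.id} for c in spec.components], "links": links}
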