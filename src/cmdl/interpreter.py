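"""The CMDL interpreter: traverse validated ASTs and execute the computations.

Interpretation materializes an :class:`~cmdl.records.ExperimentRecord`:
stoichiometry tables for batch reactions, edge weights for polymer graphs,
and propagated stream states plus residence times for flow reactions.
Validated input never fails here; interpretation of identical text is
deterministic.
"""

from __future__ import annotations

from . import flow as flow_mod
from . import polymer as polymer_mod
from . import stoichiometry as stoich_mod
from .diagnostics import Diagnostic, has_errors
from .lexer import tokenize
from .parser import AstGroup, Reference, parse
from .records import BatchReaction, ChemicalEntity, ExperimentRecord, FlowReaction, ResultMeasurement
from .units import Quantity
from .validator import validate

__all__ = ["interpret", "compile_text", "CompilationError"]


class CompilationError(ValueError):
    """Raised when interpretation is requested for a record with error diagnostics."""

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        lines = "; ".join(d.render() for d in diagnostics if d.severity.value == "error")
        super().__init__(f"record has error diagnostics: {lines}")


def _num(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, Quantity):
        return value.value
    if isinstance(value, bool):
        raise TypeError("expected a number")
    return float(value)


def _build_chemical(group: AstGroup) -> ChemicalEntity:
    return ChemicalEntity(
        name=group.name,
        smiles=group.get("smiles"),
        molar_mass=_num(group.get("molar_mass")),
        density=_num(group.get("density")),
        state=group.get("state", "solid"),
        role=group.get("role", "reagent"),
    )


def _build_polymer(group: AstGroup, fragments: dict[str, str]) -> polymer_mod.PolymerGraph:
    def build_container(g: AstGroup, prefix: str = "") -> polymer_mod.PolymerContainer:
        kind = g.get("kind", "linear")
        container = polymer_mod.PolymerContainer(id=g.name, kind=kind)
        for child in g.children():
            if child.group_type == "node":
                frag = child.get("fragment")
                if isinstance(frag, Reference):
                    frag = fragments[frag.root]
                container.children.append(
                    polymer_mod.PolymerNode(
                        id=child.name, fragment=frag, dp=_num(child.get("dp"))
                    )
                )
            elif child.group_type == "container":
                container.children.append(build_container(child, prefix + child.name + "."))
            elif child.group_type == "edge":
                src: Reference = child.get("source")
                tgt: Reference = child.get("target")
                quantity = child.get("quantity", 1.0)
                # edge endpoints are written relative to the declaring container
                container.edges.append(
                    polymer_mod.PolymerEdge(
                        source_path=prefix + ".".join(src.path[:-1]),
                        source_point=src.path[-1],
                        target_path=prefix + ".".join(tgt.path[:-1]),
                        target_point=tgt.path[-1],
                        quantity=int(quantity),
                    )
                )
        return container

    root = build_container(group)
    graph = polymer_mod.build_graph(group.name, root)
    return polymer_mod.weight_graph(graph)


def _build_reactor(group: AstGroup) -> flow_mod.ReactorGraphSpec:
    components = [
        flow_mod.ReactorComponent(
            id=c.name, kind=c.get("kind"), volume_ml=_num(c.get("volume"))
        )
        for c in group.children()
        if c.group_type == "component"
    ]
    connections = [
        (c.get("from").path[0], c.get("to").path[0])
        for c in group.children()
        if c.group_type == "connect"
    ]
    return flow_mod.ReactorGraphSpec(name=group.name, components=components, connections=connections)


def _build_reagent(group: AstGroup, chemicals: dict[str, ChemicalEntity]) -> stoich_mod.ReagentEntry:
    entity = chemicals[group.get("entity").root]
    conc = _num(group.get("concentration"))
    volume = _num(group.get("volume"))
    if conc is not None and volume is not None:
        return stoich_mod.ReagentEntry(
            entity=entity,
            solution_volume_ml=volume,
            solution_conc_M=conc,
            is_reference=bool(group.get("reference", False)),
        )
    return stoich_mod.ReagentEntry(
        entity=entity,
        mass_g=_num(group.get("mass")),
        volume_ml=volume,
        moles=_num(group.get("moles")),
        is_reference=bool(group.get("reference", False)),
    )


def _build_batch_reaction(
    group: AstGroup, chemicals: dict[str, ChemicalEntity]
) -> BatchReaction:
    entries = [
        _build_reagent(c, chemicals) for c in group.children() if c.group_type == "reagent"
    ]
    table = stoich_mod.build_table(entries)
    return BatchReaction(
        name=group.name,
        table=table,
        temperature=_num(group.get("temperature")),
        time_min=_num(group.get("time")),
    )


def _build_flow_reaction(
    group: AstGroup,
    reactors: dict[str, flow_mod.ReactorGraphSpec],
    chemicals: dict[str, ChemicalEntity],
) -> FlowReaction:
    spec = reactors[group.get("reactor").root]
    assignment: dict[str, flow_mod.InputFeed] = {}
    for inp in (c for c in group.children() if c.group_type == "input"):
        component_ref: Reference = inp.get("component")
        component_id = component_ref.path[-1]
        solution = tuple(
            (s.get("entity").root, _num(s.get("concentration")))
            for s in inp.children()
            if s.group_type == "solution"
        )
        assignment[component_id] = flow_mod.InputFeed(
            flow_ml_min=_num(inp.get("flow_rate")), solution=solution
        )
    states = flow_mod.propagate_flows(spec, assignment)
    residence = {
        c.id: flow_mod.residence_time(spec, states, c.id)
        for c in spec.components
        if c.kind == "reactor" and states[c.id].volumetric_flow_ml_min > 0
    }
    table = None
    initiators = [name for name, chem in chemicals.items() if chem.role == "initiator"]
    collections = [c.id for c in spec.components if c.kind == "collection"]
    if len(initiators) == 1 and collections:
        collected = states[collections[0]]
        if collected.molar_flows.get(initiators[0], 0.0) > 0:
            table = flow_mod.flow_stoichiometry(
                states, collections[0], initiators[0], entities=chemicals
            )
    return FlowReaction(
        name=group.name,
        reactor=spec.name,
        states=states,
        residence_times_min=residence,
        table=table,
    )


def _build_result(group: AstGroup) -> ResultMeasurement:
    conversion = group.get("conversion")
    if isinstance(conversion, Quantity):
        conversion = conversion.value
    dp_assignments = {
        ".".join(d.get("node").path[1:]): float(d.get("value"))
        for d in group.children()
        if d.group_type == "dp"
    }
    return ResultMeasurement(
        name=group.name,
        polymer=group.get("polymer").root,
        conversion=conversion,
        mn_gpc=_num(group.get("mn_gpc")),
        dispersity=_num(group.get("dispersity")),
        time_min=_num(group.get("time")),
        dp_assignments=dp_assignments,
    )


def interpret(groups: list[AstGroup]) -> ExperimentRecord:
    """Execute a validated AST into a fully materialized record."""
    diags = validate(groups)
    if has_errors(diags):
        raise CompilationError(diags)

    record = ExperimentRecord()
    fragments = {
        g.name: g.get("smiles") for g in groups if g.group_type == "fragment"
    }
    for g in groups:
        if g.group_type == "chemical":
            record.chemicals[g.name] = _build_chemical(g)
    for g in groups:
        if g.group_type in ("polymer_graph", "polymer"):
            record.polymers[g.name] = _build_polymer(g, fragments)
        elif g.group_type == "reactor_graph":
            record.reactors[g.name] = _build_reactor(g)
    for g in groups:
        if g.group_type == "reaction":
            record.reactions.append(_build_batch_reaction(g, record.chemicals))
        elif g.group_type == "flow_reaction":
            record.reactions.append(
                _build_flow_reaction(g, record.reactors, record.chemicals)
            )
        elif g.group_type == "result":
            record.results.append(_build_result(g))

    # re-weight polymer graphs with experimentally assigned DP_n from results
    for result in record.results:
        if result.dp_assignments and result.polymer in record.polymers:
            graph = record.polymers[result.polymer]
            record.polymers[result.polymer] = polymer_mod.weight_graph(
                graph, result.dp_assignments
            )
    return record


def compile_text(text: str) -> tuple[ExperimentRecord | None, list[Diagnostic]]:
    """Full pipeline: tokenize, parse, validate, interpret.

    Returns the record (None when errors block interpretation) plus every
    diagnostic collected along the way.
    """
    groups, parse_diags = parse(tokenize(text))
    diags = parse_diags + validate(groups)
    if has_errors(diags):
        return None, diags
    return interpret(groups), diags
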