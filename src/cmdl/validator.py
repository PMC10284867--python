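"""Static validation of CMDL ASTs (the compiler's type-checking stage).

Checks, per group type: required properties, quantity unit dimensions, value
vocabularies, and resolvability of every ``@reference``.  All findings are
diagnostics — validation never raises — and a record is interpretable iff
no error-severity diagnostic is produced.
"""

from __future__ import annotations

from .diagnostics import Diagnostic, error, warning
from .parser import AstGroup, AstValue, Reference
from .records import ROLES, STATES
from .units import Quantity

__all__ = ["validate"]

# property -> (expected dimension, required?) per group type
_CHEMICAL_PROPS = {
    "smiles": ("string", False),
    "molar_mass": ("molar_mass", False),
    "density": ("density", False),
    "state": ("enum:state", False),
    "role": ("enum:role", False),
}
_NODE_PROPS = {"fragment": ("string|reference", True), "dp": ("number", False)}
_EDGE_PROPS = {
    "source": ("reference", True),
    "target": ("reference", True),
    "quantity": ("number", False),
}
_CONTAINER_PROPS = {"kind": ("enum:container_kind", False)}
_COMPONENT_PROPS = {"kind": ("enum:component_kind", True), "volume": ("volume", False)}
_CONNECT_PROPS = {"from": ("reference", True), "to": ("reference", True)}
_REAGENT_PROPS = {
    "entity": ("reference", True),
    "mass": ("mass", False),
    "volume": ("volume", False),
    "moles": ("amount", False),
    "concentration": ("concentration", False),
    "reference": ("bool", False),
}
_INPUT_PROPS = {"component": ("reference", True), "flow_rate": ("flow", True)}
_SOLUTION_PROPS = {"entity": ("reference", True), "concentration": ("concentration", True)}
_RESULT_PROPS = {
    "polymer": ("reference", True),
    "conversion": ("dimensionless", False),
    "mn_gpc": ("molar_mass", False),
    "dispersity": ("number", False),
    "time": ("time", False),
}
_DP_PROPS = {"node": ("reference", True), "value": ("number", True)}
_REACTION_PROPS = {"temperature": ("temperature", False), "time": ("time", False)}
_FLOW_REACTION_PROPS = {"reactor": ("reference", True)}

_ENUMS = {
    "state": set(STATES),
    "role": set(ROLES),
    "container_kind": {"linear", "statistical"},
    "component_kind": {"input", "mixer", "reactor", "collection"},
}

_SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "chemical": _CHEMICAL_PROPS,
    "fragment": {"smiles": ("string", True)},
    "node": _NODE_PROPS,
    "edge": _EDGE_PROPS,
    "container": _CONTAINER_PROPS,
    "component": _COMPONENT_PROPS,
    "connect": _CONNECT_PROPS,
    "reagent": _REAGENT_PROPS,
    "input": _INPUT_PROPS,
    "solution": _SOLUTION_PROPS,
    "result": _RESULT_PROPS,
    "dp": _DP_PROPS,
    "reaction": _REACTION_PROPS,
    "flow_reaction": _FLOW_REACTION_PROPS,
    "polymer_graph": {},
    "polymer": {},
    "reactor_graph": {},
}

# group types whose nested groups are allowed
_ALLOWED_CHILDREN = {
    "polymer_graph": {"container", "node", "edge"},
    "polymer": {"container", "node", "edge"},
    "container": {"container", "node", "edge"},
    "reactor_graph": {"component", "connect"},
    "reaction": {"reagent"},
    "flow_reaction": {"input"},
    "input": {"solution"},
    "result": {"dp"},
}


def _check_value(
    group: AstGroup, key: str, value: AstValue, expected: str, diags: list[Diagnostic]
) -> None:
    loc = dict(line=group.line, column=group.column)
    if expected == "string":
        if not isinstance(value, str):
            diags.append(error("BAD_VALUE", f"{group.name}.{key} must be a string", **loc))
    elif expected == "string|reference":
        if not isinstance(value, (str, Reference)):
            diags.append(
                error("BAD_VALUE", f"{group.name}.{key} must be a string or reference", **loc)
            )
    elif expected == "number":
        if isinstance(value, Quantity) and value.dimension == "dimensionless":
            return
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            diags.append(error("BAD_VALUE", f"{group.name}.{key} must be a number", **loc))
    elif expected == "bool":
        if not isinstance(value, bool):
            diags.append(error("BAD_VALUE", f"{group.name}.{key} must be true/false", **loc))
    elif expected == "reference":
        if not isinstance(value, Reference):
            diags.append(error("BAD_VALUE", f"{group.name}.{key} must be a @reference", **loc))
    elif expected.startswith("enum:"):
        allowed = _ENUMS[expected.split(":", 1)[1]]
        if value not in allowed:
            diags.append(
                error("BAD_VALUE", f"{group.name}.{key} must be one of {sorted(allowed)}", **loc)
            )
    elif expected == "dimensionless":
        if isinstance(value, Quantity):
            if value.dimension != "dimensionless":
                diags.append(
                    error(
                        "WRONG_DIMENSION",
                        f"{group.name}.{key} expects a fraction or %, got {value.dimension}",
                        **loc,
                    )
                )
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            diags.append(error("BAD_VALUE", f"{group.name}.{key} must be a fraction or %", **loc))
    else:  # a physical dimension
        if isinstance(value, Quantity):
            if value.dimension != expected:
                diags.append(
                    error(
                        "WRONG_DIMENSION",
                        f"{group.name}.{key} expects {expected}, got {value.dimension}",
                        **loc,
                    )
                )
        elif expected == "molar_mass" and isinstance(value, (int, float)):
            return  # bare number read as g/mol
        else:
            diags.append(
                error("WRONG_DIMENSION", f"{group.name}.{key} expects a {expected} quantity", **loc)
            )


def _validate_group(group: AstGroup, diags: list[Diagnostic]) -> None:
    schema = _SCHEMAS.get(group.group_type)
    if schema is None:
        diags.append(
            error(
                "UNKNOWN_GROUP",
                f"unknown group type {group.group_type!r}",
                group.line,
                group.column,
            )
        )
        return
    allowed_children = _ALLOWED_CHILDREN.get(group.group_type, set())
    seen: set[str] = set()
    for key, value in group.properties:
        if isinstance(value, AstGroup):
            if value.group_type not in allowed_children:
                diags.append(
                    error(
                        "BAD_NESTING",
                        f"{value.group_type!r} group not allowed inside {group.group_type!r}",
                        value.line,
                        value.column,
                    )
                )
                continue
            _validate_group(value, diags)
            continue
        if key in seen:
            diags.append(
                error("DUPLICATE_PROPERTY", f"{group.name}.{key} declared twice", group.line, group.column)
            )
        seen.add(key)
        if key not in schema:
            diags.append(
                warning(
                    "UNKNOWN_PROPERTY",
                    f"{group.group_type} {group.name}: unrecognized property {key!r}",
                    group.line,
                    group.column,
                )
            )
            continue
        _check_value(group, key, value, schema[key][0], diags)
    for key, (_, required) in schema.items():
        if required and group.get(key) is None:
            diags.append(
                error(
                    "MISSING_PROPERTY",
                    f"{group.group_type} {group.name} lacks required property {key!r}",
                    group.line,
                    group.column,
                )
            )


def _node_paths(group: AstGroup, prefix: str = "") -> dict[str, AstGroup]:
    """Dotted node paths declared inside a polymer graph group."""
    paths: dict[str, AstGroup] = {}
    for child in group.children():
        if child.group_type == "node":
            paths[prefix + child.name] = child
        elif child.group_type == "container":
            paths.update(_node_paths(child, prefix + child.name + "."))
    return paths


def _component_ids(group: AstGroup) -> set[str]:
    return {c.name for c in group.children() if c.group_type == "component"}


def _resolve_references(groups: list[AstGroup], diags: list[Diagnostic]) -> None:
    top: dict[str, AstGroup] = {}
    for g in groups:
        if g.name in top:
            diags.append(
                error("DUPLICATE_NAME", f"{g.name!r} declared more than once", g.line, g.column)
            )
        top[g.name] = g

    def unresolved(ref: Reference, context: AstGroup, why: str) -> None:
        diags.append(
            error(
                "UNRESOLVED_REFERENCE",
                f"{context.group_type} {context.name}: {ref.text} {why}",
                context.line,
                context.column,
            )
        )

    def check_local_ref(
        ref: Reference, owner: AstGroup, context: AstGroup, prefix: str
    ) -> None:
        """Reference scoped inside a polymer or reactor graph group.

        Edge endpoints are written relative to the container declaring the
        edge; ``prefix`` is that container's dotted path within the graph.
        """
        if owner.group_type in ("polymer_graph", "polymer"):
            paths = _node_paths(owner)
            if context.group_type == "edge":
                # last component is the attachment letter
                if len(ref.path) < 2 or prefix + ".".join(ref.path[:-1]) not in paths:
                    unresolved(ref, context, "does not name node.LETTER in this graph")
            elif prefix + ".".join(ref.path) not in paths:
                unresolved(ref, context, "does not name a node in this graph")
        elif owner.group_type == "reactor_graph":
            if ref.path[0] not in _component_ids(owner):
                unresolved(ref, context, "does not name a component in this reactor graph")

    def walk(group: AstGroup, owner: AstGroup | None, prefix: str) -> None:
        next_owner = (
            group
            if group.group_type in ("polymer_graph", "polymer", "reactor_graph")
            else owner
        )
        for key, value in group.properties:
            if isinstance(value, AstGroup):
                base = "" if next_owner is group else prefix  # scope resets at a graph group
                child_prefix = (
                    base + value.name + "." if value.group_type == "container" else base
                )
                walk(value, next_owner, child_prefix)
            elif isinstance(value, Reference):
                if next_owner is not None and group.group_type in ("edge", "connect"):
                    check_local_ref(value, next_owner, group, prefix)
                elif value.root in top:
                    _check_cross_reference(value, group, top, diags)
                else:
                    unresolved(value, group, "is not declared")

    for g in groups:
        walk(g, None, "")


def _check_cross_reference(
    ref: Reference, context: AstGroup, top: dict[str, AstGroup], diags: list[Diagnostic]
) -> None:
    target = top[ref.root]
    if len(ref.path) == 1:
        return
    if target.group_type in ("polymer_graph", "polymer"):
        paths = _node_paths(target)
        if ".".join(ref.path[1:]) not in paths:
            diags.append(
                error(
                    "UNRESOLVED_REFERENCE",
                    f"{context.group_type} {context.name}: {ref.text} names no node of {ref.root!r}",
                    context.line,
                    context.column,
                )
            )
    elif target.group_type == "reactor_graph":
        if ref.path[1] not in _component_ids(target):
            diags.append(
                error(
                    "UNRESOLVED_REFERENCE",
                    f"{context.group_type} {context.name}: {ref.text} names no component of {ref.root!r}",
                    context.line,
                    context.column,
                )
            )


def _check_reactions(groups: list[AstGroup], diags: list[Diagnostic]) -> None:
    top = {g.name: g for g in groups}
    for g in groups:
        if g.group_type != "reaction":
            continue
        for reagent in (c for c in g.children() if c.group_type == "reagent"):
            entity_ref = reagent.get("entity")
            if not isinstance(entity_ref, Reference) or entity_ref.root not in top:
                continue
            chem = top[entity_ref.root]
            if chem.group_type != "chemical":
                continue
            needs_molar_mass = reagent.get("mass") is not None or (
                reagent.get("volume") is not None and reagent.get("concentration") is None
            )
            if needs_molar_mass and chem.get("molar_mass") is None:
                diags.append(
                    error(
                        "MISSING_MOLAR_MASS",
                        f"chemical {chem.name!r} is used by mass in reaction {g.name!r} "
                        "but declares no molar_mass",
                        reagent.line,
                        reagent.column,
                    )
                )


def validate(groups: list[AstGroup]) -> list[Diagnostic]:
    """Run all static checks; empty result means the record is interpretable."""
    diags: list[Diagnostic] = []
    for g in groups:
        if g.group_type not in _SCHEMAS or g.group_type in (
            "node",
            "edge",
            "container",
            "component",
            "connect",
            "reagent",
            "input",
            "solution",
            "dp",
        ):
            diags.append(
                error(
                    "UNKNOWN_GROUP",
                    f"{g.group_type!r} cannot appear at top level",
                    g.line,
                    g.column,
                )
            )
            continue
        _validate_group(g, diags)
    _resolve_references(groups, diags)
    _check_reactions(groups, diags)
    return diags
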