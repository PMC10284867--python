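"""Quality control of model-generated polymer-graph strings.

Generative models emitting serialized polymer graphs fail in characteristic
ways: truncated or chemically impossible SMILES fragments, repeat units that
lost an attachment point and can no longer enchain, connectivity that admits
more than one architectural reading, or verbatim reproduction of the
training corpus.  ``qc_string`` triages each generated line into exactly one
category, in a fixed precedence order (a syntactically dead string cannot be
judged chemically, and so on):

1. ``invalid_syntax`` — the string does not parse into a graph;
2. ``invalid_chemistry`` — a node fragment fails valence/ring validation;
3. ``invalid_repeat_structure`` — a repeat unit exposes fewer than two
   attachment points, or an edge names a letter its node does not declare;
4. ``ambiguous_connectivity`` — the inter-repeat edges admit both a block
   and a statistical reading; resolved as the AB block architecture;
5. ``valid_reproduction`` / ``valid_novel`` — canonical-structure membership
   in the reference corpus decides novelty (weights are stripped first, so
   novelty is structural, not a matter of re-printed weights).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .polymer import (
    PolymerContainer,
    PolymerGraph,
    PolymerNode,
    canonical_graph_string,
    parse_graph_string,
    validate_fragment,
)

__all__ = ["QC_CATEGORIES", "QCReport", "qc_string", "qc_batch", "preservation_check"]

QC_CATEGORIES = (
    "valid_novel",
    "valid_reproduction",
    "invalid_syntax",
    "invalid_chemistry",
    "invalid_repeat_structure",
    "ambiguous_connectivity",
)


@dataclass
class QCReport:
    input: str
    category: str
    details: list[str] = field(default_factory=list)
    resolved_graph: Optional[PolymerGraph] = None

    def as_dict(self) -> dict:
        return {"input": self.input, "category": self.category, "details": self.details}


def _repeat_nodes(graph: PolymerGraph) -> dict[str, PolymerNode]:
    """Nodes acting as repeat units: self-edge endpoints or statistical members."""
    repeats: dict[str, PolymerNode] = {}
    nodes = dict(graph.iter_nodes())
    for edge in graph.iter_edges():
        if edge.is_self_edge:
            repeats[edge.source_path] = nodes[edge.source_path]

    def visit(container: PolymerContainer, prefix: str) -> None:
        for child in container.children:
            if isinstance(child, PolymerNode):
                if container.kind == "statistical":
                    repeats[prefix + child.id] = child
            else:
                visit(child, prefix + child.id + ".")

    visit(graph.root, "")
    return repeats


def _ambiguous_pairs(graph: PolymerGraph) -> list[tuple[str, str]]:
    """Pairs of repeat nodes connected by edges in both directions.

    A single junction edge reads as a block boundary; edges both ways between
    two self-propagating repeat units are consistent with either a block or a
    statistical (random enchainment) architecture, unless the container is
    explicitly marked statistical.
    """
    repeats = set(_repeat_nodes(graph))
    stat_members: set[str] = set()

    def visit(container: PolymerContainer, prefix: str) -> None:
        for child in container.children:
            if isinstance(child, PolymerNode):
                if container.kind == "statistical":
                    stat_members.add(prefix + child.id)
            else:
                visit(child, prefix + child.id + ".")

    visit(graph.root, "")
    directed: set[tuple[str, str]] = set()
    for edge in graph.iter_edges():
        if edge.is_self_edge:
            continue
        if edge.source_path in repeats and edge.target_path in repeats:
            directed.add((edge.source_path, edge.target_path))
    pairs = []
    for a, b in directed:
        if (b, a) in directed and a < b and not {a, b} <= stat_members:
            pairs.append((a, b))
    return pairs


def _resolve_as_block(graph: PolymerGraph, pairs: list[tuple[str, str]]) -> PolymerGraph:
    """Keep one junction edge per ambiguous pair (the lexicographically first
    direction), yielding the AB block reading."""
    drop: set[tuple] = set()
    for a, b in pairs:
        for edge in graph.iter_edges():
            if edge.source_path == b and edge.target_path == a:
                drop.add(edge.key())

    def rebuild(container: PolymerContainer) -> PolymerContainer:
        return PolymerContainer(
            id=container.id,
            kind=container.kind,
            children=[
                c if isinstance(c, PolymerNode) else rebuild(c) for c in container.children
            ],
            edges=[e for e in container.edges if e.key() not in drop],
        )

    return PolymerGraph(name=graph.name, root=rebuild(graph.root))


def qc_string(s: str, reference_set: Iterable[str] = ()) -> QCReport:
    """Classify one generated polymer-graph string.

    ``reference_set`` holds canonical graph strings of the training corpus
    (see :func:`cmdl.polymer.canonical_graph_string`); membership separates
    reproductions from novel structures.
    """
    outcome = parse_graph_string(s)
    if not outcome.ok:
        return QCReport(
            input=s,
            category="invalid_syntax",
            details=[f"{outcome.failure.kind}: {outcome.failure.message}"],
        )
    graph = outcome.graph

    bad_fragments = []
    for path, node in graph.iter_nodes():
        ok, reason = validate_fragment(node.fragment)
        if not ok:
            bad_fragments.append(f"{path}: {reason}")
    if bad_fragments:
        return QCReport(input=s, category="invalid_chemistry", details=bad_fragments)

    structure_findings = []
    for path, node in _repeat_nodes(graph).items():
        points = node.attachment_points
        if sum(points.values()) < 2:
            structure_findings.append(
                f"repeat unit {path} exposes {sum(points.values())} attachment point(s)"
            )
    for edge in graph.iter_edges():
        for path, letter in (
            (edge.source_path, edge.source_point),
            (edge.target_path, edge.target_point),
        ):
            node = dict(graph.iter_nodes()).get(path)
            if node is not None and letter not in node.attachment_points:
                structure_findings.append(f"edge names letter {letter} absent from {path}")
    if structure_findings:
        return QCReport(input=s, category="invalid_repeat_structure", details=structure_findings)

    pairs = _ambiguous_pairs(graph)
    if pairs:
        resolved = _resolve_as_block(graph, pairs)
        return QCReport(
            input=s,
            category="ambiguous_connectivity",
            details=[f"block/statistical ambiguity between {a} and {b}" for a, b in pairs],
            resolved_graph=resolved,
        )

    canonical = canonical_graph_string(graph)
    if canonical in set(reference_set):
        return QCReport(
            input=s,
            category="valid_reproduction",
            details=["canonical structure present in reference corpus"],
            resolved_graph=graph,
        )
    return QCReport(input=s, category="valid_novel", resolved_graph=graph)


def qc_batch(
    lines: Iterable[str], reference_set: Iterable[str] = ()
) -> tuple[Counter, list[QCReport]]:
    """Classify a stream of generated strings; counts sum to the number of
    non-empty lines."""
    reference = set(reference_set)
    reports = [qc_string(line, reference) for line in lines if line.strip()]
    counts = Counter(r.category for r in reports)
    return counts, reports


def preservation_check(
    generated: PolymerGraph, seed: PolymerGraph
) -> tuple[bool, list[str]]:
    """Did a generated graph preserve the seed's attachment points and topology?

    True iff every node path of the seed exists in the generated graph with
    the same attachment-point letters and counts, and the edge set (endpoints,
    letters, quantities — weights ignored) is unchanged.  The diff lists
    fragment-interior substitutions (allowed) and any structural changes
    (which make the check fail).
    """
    diff: list[str] = []
    ok = True
    seed_nodes = dict(seed.iter_nodes())
    gen_nodes = dict(generated.iter_nodes())
    for path in sorted(set(seed_nodes) | set(gen_nodes)):
        if path not in gen_nodes:
            diff.append(f"node removed: {path}")
            ok = False
            continue
        if path not in seed_nodes:
            diff.append(f"node added: {path}")
            ok = False
            continue
        s, g = seed_nodes[path], gen_nodes[path]
        if s.attachment_points != g.attachment_points:
            diff.append(
                f"attachment points changed on {path}: "
                f"{s.attachment_points} -> {g.attachment_points}"
            )
            ok = False
        elif s.fragment != g.fragment:
            diff.append(f"fragment modified on {path}: {s.fragment} -> {g.fragment}")
    seed_edges = {(e.key(), e.quantity) for e in seed.iter_edges()}
    gen_edges = {(e.key(), e.quantity) for e in generated.iter_edges()}
    for key, q in sorted(seed_edges - gen_edges):
        diff.append(f"edge removed: {key} x{q}")
        ok = False
    for key, q in sorted(gen_edges - seed_edges):
        diff.append(f"edge added: {key} x{q}")
        ok = False
    return ok, diff
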