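"""Stochastic polymer graphs: nodes, edges, containers, and edge weights.

A polymer is represented as a graph whose nodes are SMILES fragments with
non-atomic attachment-point placeholders (``[R]``, ``[Q]``, ``[X]``, ``[Z]``)
and whose edges name a source and target attachment point.  Assigning a
degree of polymerization (DP_n) to each repeat node lets the interpreter
compute, for every edge, the fraction of all covalent bonds in the stochastic
chain that belong to that bond type (the *edge weight*).

The computation goes through an intermediate *composite tree*: a hierarchy
of containers (linear or statistical), node leaves carrying DP_n, and edge
leaves carrying bond-occurrence counts.  Counting rules:

* self-edge of a repeat node with DP_n = n and edge quantity q counts
  ``q * (n - 1)`` bonds (the bonds inside each of the q symmetric arms);
* a junction edge (end group to repeat unit, or block to block) counts
  ``q`` bonds, or 0 when either endpoint has DP_n = 0 (failed polymerization);
* inside a statistical container with member DP_n values summing to N, the
  N - 1 internal bonds are apportioned by expected random-enchainment
  frequencies: ``(N-1) * f_x**2`` for a like pair and ``(N-1) * 2 f_x f_y``
  for an unlike pair, with ``f_x = dp_x / N`` (edge direction ignored).

Weights are the counts normalized by the total count over the whole graph,
so they always sum to 1 (except the degenerate bond-free graph, where every
weight is 0).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

import networkx as nx
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PLACEHOLDER_LETTERS",
    "PolymerNode",
    "PolymerEdge",
    "PolymerContainer",
    "PolymerGraph",
    "CompositeTree",
    "PolymerGraphError",
    "GraphStringFailure",
    "GraphStringOutcome",
    "attachment_points_of",
    "validate_fragment",
    "fragment_to_wildcard_smiles",
    "canonical_fragment",
    "build_graph",
    "to_composite_tree",
    "compute_edge_weights",
    "weight_graph",
    "serialize_graph_string",
    "parse_graph_string",
    "canonical_graph_string",
    "graphs_equal",
]

PLACEHOLDER_LETTERS = ("R", "Q", "X", "Z")
_PLACEHOLDER_RE = re.compile(r"\[(R|Q|X|Z)\]")
# stable atom-map number per placeholder letter, for canonicalization
_LETTER_MAP = {letter: i + 1 for i, letter in enumerate(PLACEHOLDER_LETTERS)}
_MAP_LETTER = {v: k for k, v in _LETTER_MAP.items()}


class PolymerGraphError(ValueError):
    """Structural error in a polymer graph definition."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class PolymerNode:
    """A discrete structural element (end group, repeat unit, branch point)."""

    id: str
    fragment: str
    dp: Optional[float] = None

    @property
    def attachment_points(self) -> dict[str, int]:
        return attachment_points_of(self.fragment)

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise PolymerGraphError(f"node {self.id!r}: DP_n must be >= 0, got {self.dp}")
        if not attachment_points_of(self.fragment) and _PLACEHOLDER_RE.search(self.fragment):
            raise PolymerGraphError(f"node {self.id!r}: malformed placeholders")


@dataclass
class PolymerEdge:
    """A bond type between two attachment points.

    ``quantity`` compresses symmetric identical branches (a diol initiator,
    dendrimer generations) into one edge; ``weight`` is filled in by
    :func:`compute_edge_weights`.
    """

    source_path: str
    source_point: str
    target_path: str
    target_point: str
    quantity: int = 1
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.quantity < 1:
            raise PolymerGraphError("edge quantity must be >= 1")
        for letter in (self.source_point, self.target_point):
            if letter not in PLACEHOLDER_LETTERS:
                raise PolymerGraphError(f"unknown attachment letter {letter!r}")

    @property
    def is_self_edge(self) -> bool:
        return self.source_path == self.target_path

    def key(self) -> tuple[str, str, str, str]:
        return (self.source_path, self.source_point, self.target_path, self.target_point)


@dataclass
class PolymerContainer:
    """Grouping element: ordered children (nodes or containers) plus edges.

    ``kind`` is ``linear`` for block-like enchainment or ``statistical`` for
    random enchainment of the member repeat units.
    """

    id: str
    kind: str = "linear"
    children: list[Union[PolymerNode, "PolymerContainer"]] = field(default_factory=list)
    edges: list[PolymerEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "statistical"):
            raise PolymerGraphError(f"container kind must be linear|statistical, got {self.kind!r}")
        seen: set[str] = set()
        for child in self.children:
            if child.id in seen:
                raise PolymerGraphError(f"duplicate child id {child.id!r} in container {self.id!r}")
            seen.add(child.id)


@dataclass
class PolymerGraph:
    name: str
    root: PolymerContainer

    # -- navigation -----------------------------------------------------
    def iter_nodes(self) -> Iterator[tuple[str, PolymerNode]]:
        """Yield (dotted path, node) in depth-first container order."""
        yield from _iter_nodes(self.root, prefix="")

    def iter_edges(self) -> Iterator[PolymerEdge]:
        yield from _iter_edges(self.root, prefix="")

    def node(self, path: str) -> PolymerNode:
        for p, n in self.iter_nodes():
            if p == path:
                return n
        raise PolymerGraphError(f"no node at path {path!r}")

    def node_paths(self) -> list[str]:
        return [p for p, _ in self.iter_nodes()]


def _iter_nodes(container: PolymerContainer, prefix: str) -> Iterator[tuple[str, PolymerNode]]:
    for child in container.children:
        if isinstance(child, PolymerNode):
            yield (prefix + child.id, child)
        else:
            yield from _iter_nodes(child, prefix + child.id + ".")


def _iter_edges(container: PolymerContainer, prefix: str) -> Iterator[PolymerEdge]:
    for edge in container.edges:
        yield edge
    for child in container.children:
        if isinstance(child, PolymerContainer):
            yield from _iter_edges(child, prefix + child.id + ".")


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


def attachment_points_of(fragment: str) -> dict[str, int]:
    """Count placeholder letters in a fragment, e.g. ``{"R": 1, "Q": 1}``."""
    counts: dict[str, int] = {}
    for m in _PLACEHOLDER_RE.finditer(fragment):
        counts[m.group(1)] = counts.get(m.group(1), 0) + 1
    return counts


def fragment_to_wildcard_smiles(fragment: str) -> str:
    """Replace placeholder tokens with atom-mapped wildcard atoms (``[*:n]``)."""
    return _PLACEHOLDER_RE.sub(lambda m: f"[*:{_LETTER_MAP[m.group(1)]}]", fragment)


def _ring_digits_balanced(smiles: str) -> bool:
    # ring-bond numbers must each occur an even number of times
    body = re.sub(r"\[[^\]]*\]", "A", smiles)  # bracket atoms cannot open rings via digits inside
    counts: dict[str, int] = {}
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "%" and i + 2 < len(body) and body[i + 1 : i + 3].isdigit():
            counts[body[i + 1 : i + 3]] = counts.get(body[i + 1 : i + 3], 0) + 1
            i += 3
            continue
        if ch.isdigit():
            counts[ch] = counts.get(ch, 0) + 1
        i += 1
    return all(v % 2 == 0 for v in counts.values())


def validate_fragment(fragment: str) -> tuple[bool, str]:
    """Check a placeholder fragment for chemical validity.

    Placeholders are substituted by wildcard atoms and the result must parse
    and sanitize under standard valence rules.  Returns ``(ok, reason)`` with
    reason one of ``OK``, ``EMPTY``, ``PAREN``, ``RING``, ``SYNTAX``,
    ``VALENCE``, ``CHEMISTRY``.
    """
    if not fragment or not fragment.strip():
        return False, "EMPTY"
    smiles = _PLACEHOLDER_RE.sub("[*]", fragment)
    if smiles.count("(") != smiles.count(")"):
        return False, "PAREN"
    if not _ring_digits_balanced(smiles):
        return False, "RING"
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return False, "SYNTAX"
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several sanitization error types
        reason = "VALENCE" if "valence" in str(exc).lower() else "CHEMISTRY"
        return False, reason
    return True, "OK"


def canonical_fragment(fragment: str) -> str:
    """Canonical form of a placeholder fragment (via RDKit canonical SMILES).

    Identical repeat units written with different atom orders map to the
    same string, which is what dataset grouping and novelty checks key on.
    """
    ok, reason = validate_fragment(fragment)
    if not ok:
        raise PolymerGraphError(f"cannot canonicalize invalid fragment ({reason}): {fragment!r}")
    mol = Chem.MolFromSmiles(fragment_to_wildcard_smiles(fragment))
    canonical = Chem.MolToSmiles(mol)
    return re.sub(
        r"\[\*:(\d+)\]", lambda m: f"[{_MAP_LETTER[int(m.group(1))]}]", canonical
    )


# ---------------------------------------------------------------------------
# graph construction & validation
# ---------------------------------------------------------------------------


def build_graph(name: str, root: PolymerContainer) -> PolymerGraph:
    """Assemble and structurally validate a polymer graph.

    Checks that every edge endpoint resolves to a declared node, that the
    referenced attachment letters exist on those nodes, and that the edges
    connect the graph.
    """
    graph = PolymerGraph(name=name, root=root)
    paths = dict(graph.iter_nodes())
    if not paths:
        raise PolymerGraphError(f"polymer graph {name!r} has no nodes")
    for edge in graph.iter_edges():
        for path, letter in ((edge.source_path, edge.source_point), (edge.target_path, edge.target_point)):
            if path not in paths:
                raise PolymerGraphError(f"edge endpoint {path!r} is not a declared node")
            if letter not in paths[path].attachment_points:
                raise PolymerGraphError(
                    f"node {path!r} has no attachment point {letter!r} "
                    f"(declares {sorted(paths[path].attachment_points)})"
                )
    if len(paths) > 1:
        g = nx.Graph()
        g.add_nodes_from(paths)
        for edge in graph.iter_edges():
            g.add_edge(edge.source_path, edge.target_path)
        if not nx.is_connected(g):
            raise PolymerGraphError(f"polymer graph {name!r} is not connected")
    return graph


# ---------------------------------------------------------------------------
# composite tree & edge weights
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    path: str
    node: PolymerNode
    dp: float


@dataclass
class TreeEdge:
    edge: PolymerEdge
    count: float = 0.0


@dataclass
class TreeContainer:
    id: str
    kind: str
    children: list[Union[TreeNode, "TreeContainer"]] = field(default_factory=list)
    edges: list[TreeEdge] = field(default_factory=list)


@dataclass
class CompositeTree:
    """Intermediate hierarchical form used to compute edge weights."""

    graph: PolymerGraph
    root: TreeContainer

    def iter_edges(self) -> Iterator[TreeEdge]:
        yield from _iter_tree_edges(self.root)

    def iter_tree_nodes(self) -> Iterator[TreeNode]:
        yield from _iter_tree_nodes(self.root)

    def total_count(self) -> float:
        return sum(te.count for te in self.iter_edges())


def _iter_tree_edges(container: TreeContainer) -> Iterator[TreeEdge]:
    yield from container.edges
    for child in container.children:
        if isinstance(child, TreeContainer):
            yield from _iter_tree_edges(child)


def _iter_tree_nodes(container: TreeContainer) -> Iterator[TreeNode]:
    for child in container.children:
        if isinstance(child, TreeNode):
            yield child
        else:
            yield from _iter_tree_nodes(child)


def _repeat_paths(graph: PolymerGraph) -> set[str]:
    """Nodes that behave as repeat units: self-edge endpoints and members of
    statistical containers."""
    repeats = {e.source_path for e in graph.iter_edges() if e.is_self_edge}

    def visit(container: PolymerContainer, prefix: str) -> None:
        for child in container.children:
            if isinstance(child, PolymerNode):
                if container.kind == "statistical":
                    repeats.add(prefix + child.id)
            else:
                visit(child, prefix + child.id + ".")

    visit(graph.root, "")
    return repeats


def to_composite_tree(
    graph: PolymerGraph, dp_assignments: Optional[dict[str, float]] = None
) -> CompositeTree:
    """Mirror the container hierarchy and attach DP_n values to node leaves.

    ``dp_assignments`` (node path -> DP_n) overrides DP_n declared on the
    nodes themselves.  A node with neither defaults to DP_n = 1 (a single
    unit: end groups, and the degenerate one-unit chain for repeat nodes).
    """
    dp_assignments = dict(dp_assignments or {})
    for path, dp in dp_assignments.items():
        if dp < 0:
            raise PolymerGraphError(f"DP_n must be >= 0, got {dp} for {path!r}")

    def build(container: PolymerContainer, prefix: str) -> TreeContainer:
        tc = TreeContainer(id=container.id, kind=container.kind)
        for child in container.children:
            if isinstance(child, PolymerNode):
                path = prefix + child.id
                dp = dp_assignments.get(path, child.dp if child.dp is not None else 1.0)
                if dp < 0:
                    raise PolymerGraphError(f"DP_n must be >= 0, got {dp} for {path!r}")
                tc.children.append(TreeNode(path=path, node=child, dp=float(dp)))
            else:
                tc.children.append(build(child, prefix + child.id + "."))
        tc.edges = [TreeEdge(edge=e) for e in container.edges]
        return tc

    return CompositeTree(graph=graph, root=build(graph.root, ""))


def _assign_counts(tree: CompositeTree) -> None:
    dp_by_path = {tn.path: tn.dp for tn in tree.iter_tree_nodes()}

    def members_of(container: TreeContainer) -> list[TreeNode]:
        out: list[TreeNode] = []
        for child in container.children:
            if isinstance(child, TreeNode):
                out.append(child)
            else:
                out.extend(members_of(child))
        return out

    def visit(container: TreeContainer) -> None:
        if container.kind == "statistical":
            _statistical_counts(container, dp_by_path)
        else:
            for te in container.edges:
                edge = te.edge
                if edge.is_self_edge:
                    dp = dp_by_path.get(edge.source_path, 1.0)
                    te.count = edge.quantity * max(dp - 1.0, 0.0)
                else:
                    src_dp = dp_by_path.get(edge.source_path, 1.0)
                    tgt_dp = dp_by_path.get(edge.target_path, 1.0)
                    te.count = float(edge.quantity) if src_dp > 0 and tgt_dp > 0 else 0.0
        for child in container.children:
            if isinstance(child, TreeContainer):
                visit(child)

    visit(tree.root)


def _statistical_counts(container: TreeContainer, dp_by_path: dict[str, float]) -> None:
    """Apportion a statistical container's internal bonds to its edges.

    With member DP_n values summing to N there are N - 1 internal bonds.
    Under random enchainment the expected fraction of x-x bonds is f_x**2
    and of x-y bonds 2 f_x f_y (f_x = dp_x / N); edges are unordered, so a
    pair declared in both directions shares its count equally.
    """
    member_paths = [
        child.path for child in container.children if isinstance(child, TreeNode)
    ]
    total_dp = sum(dp_by_path.get(p, 1.0) for p in member_paths)
    internal_bonds = max(total_dp - 1.0, 0.0)

    internal: dict[frozenset, list[TreeEdge]] = {}
    for te in container.edges:
        edge = te.edge
        if edge.source_path in member_paths and edge.target_path in member_paths:
            internal.setdefault(frozenset((edge.source_path, edge.target_path)), []).append(te)
        else:
            # junction into/out of the statistical block
            src_dp = dp_by_path.get(edge.source_path, 1.0)
            tgt_dp = dp_by_path.get(edge.target_path, 1.0)
            te.count = float(edge.quantity) if src_dp > 0 and tgt_dp > 0 else 0.0

    if total_dp <= 0:
        for edges in internal.values():
            for te in edges:
                te.count = 0.0
        return
    for pair, edges in internal.items():
        paths = sorted(pair)
        if len(paths) == 1:
            fx = dp_by_path.get(paths[0], 1.0) / total_dp
            pair_count = internal_bonds * fx * fx
        else:
            fx = dp_by_path.get(paths[0], 1.0) / total_dp
            fy = dp_by_path.get(paths[1], 1.0) / total_dp
            pair_count = internal_bonds * 2.0 * fx * fy
        for te in edges:
            te.count = pair_count / len(edges)


def compute_edge_weights(tree: CompositeTree) -> PolymerGraph:
    """Normalize bond-occurrence counts into edge weights on a copy of the graph.

    Weights over the whole graph sum to 1; if the graph implies no bonds at
    all (all DP_n <= 1, no junctions) every weight is 0 and a warning is
    emitted.
    """
    _assign_counts(tree)
    total = tree.total_count()
    weights: dict[tuple, float] = {}
    for te in tree.iter_edges():
        weights[te.edge.key()] = (te.count / total) if total > 0 else 0.0
    if total <= 0:
        warnings.warn("polymer graph implies zero bonds; all edge weights set to 0", stacklevel=2)

    # repeat nodes carry their effective DP_n on the weighted graph; other
    # nodes keep whatever was declared (usually nothing)
    repeats = _repeat_paths(tree.graph)
    effective_dp = {tn.path: tn.dp for tn in tree.iter_tree_nodes()}

    def copy_container(container: PolymerContainer, prefix: str) -> PolymerContainer:
        children: list[Union[PolymerNode, PolymerContainer]] = []
        for c in container.children:
            if isinstance(c, PolymerNode):
                path = prefix + c.id
                dp = effective_dp[path] if path in repeats else c.dp
                children.append(replace(c, dp=dp))
            else:
                children.append(copy_container(c, prefix + c.id + "."))
        return PolymerContainer(
            id=container.id,
            kind=container.kind,
            children=children,
            edges=[replace(e, weight=weights[e.key()]) for e in container.edges],
        )

    return PolymerGraph(name=tree.graph.name, root=copy_container(tree.graph.root, ""))


def weight_graph(
    graph: PolymerGraph, dp_assignments: Optional[dict[str, float]] = None
) -> PolymerGraph:
    """Convenience: composite tree plus weight computation in one call."""
    return compute_edge_weights(to_composite_tree(graph, dp_assignments))


# ---------------------------------------------------------------------------
# graph-string serialization (ML I/O)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphStringFailure:
    kind: str  # EMPTY | UNBALANCED_SMILES | BAD_NODE | BAD_EDGE | UNKNOWN_LETTER | DANGLING_EDGE | BAD_TAG
    message: str


@dataclass
class GraphStringOutcome:
    graph: Optional[PolymerGraph] = None
    properties: dict[str, str] = field(default_factory=dict)
    failure: Optional[GraphStringFailure] = None

    @property
    def ok(self) -> bool:
        return self.graph is not None


def _node_sort_key(graph: PolymerGraph) -> dict[str, tuple]:
    """Canonical order: depth-first container order, then lexicographic id."""
    order: dict[str, tuple] = {}

    def visit(container: PolymerContainer, prefix: str, index: tuple) -> None:
        nodes = sorted(
            (c for c in container.children if isinstance(c, PolymerNode)), key=lambda n: n.id
        )
        for i, node in enumerate(nodes):
            order[prefix + node.id] = index + (i,)
        subs = [c for c in container.children if isinstance(c, PolymerContainer)]
        for j, sub in enumerate(subs):
            visit(sub, prefix + sub.id + ".", index + (len(nodes) + j,))

    visit(graph.root, "", ())
    return order


def serialize_graph_string(
    graph: PolymerGraph, properties: Optional[dict[str, object]] = None
) -> str:
    """Serialize a polymer graph to a canonical single-line string.

    Layout: property tags, structure tags, node terms ``path(fragment)``,
    then edge terms ``<src.L|tgt.L|weight>`` (weight omitted when absent,
    quantity > 1 rendered as an ``xQ`` field).  Statistical containers are
    recorded as ``<stat:path>`` tags so parsing is lossless.  Equal graphs
    serialize identically.
    """
    terms: list[str] = [f"<graph:{graph.name}>"]
    for key in sorted(properties or {}):
        terms.append(f"<{key}:{properties[key]}>")

    stat_paths: list[str] = []

    def find_stats(container: PolymerContainer, prefix: str) -> None:
        for child in container.children:
            if isinstance(child, PolymerContainer):
                path = prefix + child.id
                if child.kind == "statistical":
                    stat_paths.append(path)
                find_stats(child, path + ".")

    find_stats(graph.root, "")
    terms.extend(f"<stat:{p}>" for p in sorted(stat_paths))

    order = _node_sort_key(graph)
    nodes = sorted(graph.iter_nodes(), key=lambda item: order[item[0]])
    for path, node in nodes:
        dp_tag = "" if node.dp is None else f"{{dp:{_fmt_num(node.dp)}}}"
        terms.append(f"{path}({node.fragment}){dp_tag}")

    edges = sorted(graph.iter_edges(), key=lambda e: e.key())
    for edge in edges:
        fields = [
            f"{edge.source_path}.{edge.source_point}",
            f"{edge.target_path}.{edge.target_point}",
        ]
        if edge.quantity != 1:
            fields.append(f"x{edge.quantity}")
        if edge.weight is not None:
            fields.append(f"{edge.weight:.4f}")
        terms.append("<" + "|".join(fields) + ">")
    return " ".join(terms)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


_TAG_RE = re.compile(r"<([A-Za-z_][A-Za-z0-9_\-]*):([^>|]*)>")
_NODE_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_.\-]*)\(")
_EDGE_POINT_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_.\-]*)\.([A-Z])$")


def parse_graph_string(text: str) -> GraphStringOutcome:
    """Parse a serialized polymer-graph string; never raises.

    Inverse of :func:`serialize_graph_string` on its image.  Malformed input
    yields a :class:`GraphStringFailure` whose ``kind`` names the defect —
    the classification that downstream generated-structure QC consumes.
    """
    text = text.strip()
    if not text:
        return GraphStringOutcome(failure=GraphStringFailure("EMPTY", "empty graph string"))

    name = "polymer"
    properties: dict[str, str] = {}
    stat_paths: set[str] = set()
    nodes: list[tuple[str, str, Optional[float]]] = []  # (path, fragment, dp)
    edges: list[PolymerEdge] = []

    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        if text[i] == "<":
            end = text.find(">", i)
            if end == -1:
                return GraphStringOutcome(
                    failure=GraphStringFailure("BAD_EDGE", f"unterminated '<' at {i}")
                )
            body = text[i + 1 : end]
            tag = _TAG_RE.fullmatch(text[i : end + 1])
            if tag and "|" not in body:
                key, value = tag.group(1), tag.group(2)
                if key == "graph":
                    name = value
                elif key == "stat":
                    stat_paths.add(value)
                else:
                    properties[key] = value
            else:
                fields = body.split("|")
                if len(fields) < 2:
                    return GraphStringOutcome(
                        failure=GraphStringFailure("BAD_EDGE", f"edge term needs '|': <{body}>")
                    )
                sm = _EDGE_POINT_RE.fullmatch(fields[0].strip())
                tm = _EDGE_POINT_RE.fullmatch(fields[1].strip())
                if not sm or not tm:
                    return GraphStringOutcome(
                        failure=GraphStringFailure(
                            "BAD_EDGE", f"malformed edge endpoints: <{body}>"
                        )
                    )
                if sm.group(2) not in PLACEHOLDER_LETTERS or tm.group(2) not in PLACEHOLDER_LETTERS:
                    return GraphStringOutcome(
                        failure=GraphStringFailure(
                            "UNKNOWN_LETTER", f"attachment letter outside R/Q/X/Z: <{body}>"
                        )
                    )
                quantity, weight = 1, None
                for extra in fields[2:]:
                    extra = extra.strip()
                    if extra.startswith("x") and extra[1:].isdigit():
                        quantity = int(extra[1:])
                    else:
                        try:
                            weight = float(extra)
                        except ValueError:
                            return GraphStringOutcome(
                                failure=GraphStringFailure(
                                    "BAD_EDGE", f"bad edge field {extra!r}: <{body}>"
                                )
                            )
                edges.append(
                    PolymerEdge(
                        source_path=sm.group(1),
                        source_point=sm.group(2),
                        target_path=tm.group(1),
                        target_point=tm.group(2),
                        quantity=quantity,
                        weight=weight,
                    )
                )
            i = end + 1
            continue
        m = _NODE_RE.match(text, i)
        if m:
            # fragment runs to the parenthesis matching the opener
            depth = 1
            j = m.end()
            while j < n and depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                return GraphStringOutcome(
                    failure=GraphStringFailure(
                        "UNBALANCED_SMILES", f"node {m.group(1)!r} fragment misses ')'"
                    )
                )
            fragment = text[m.end() : j - 1]
            dp: Optional[float] = None
            if text[j : j + 1] == "{":
                close = text.find("}", j)
                if close == -1:
                    return GraphStringOutcome(
                        failure=GraphStringFailure("BAD_NODE", "unterminated node annotation")
                    )
                ann = text[j + 1 : close]
                if ann.startswith("dp:"):
                    try:
                        dp = float(ann[3:])
                    except ValueError:
                        return GraphStringOutcome(
                            failure=GraphStringFailure("BAD_NODE", f"bad dp annotation {ann!r}")
                        )
                j = close + 1
            nodes.append((m.group(1), fragment, dp))
            i = j
            continue
        return GraphStringOutcome(
            failure=GraphStringFailure("BAD_NODE", f"cannot read term at position {i}: {text[i:i+20]!r}")
        )

    if not nodes:
        return GraphStringOutcome(failure=GraphStringFailure("BAD_NODE", "no node terms"))

    try:
        graph = _assemble(name, nodes, edges, stat_paths)
    except PolymerGraphError as exc:
        return GraphStringOutcome(failure=GraphStringFailure("DANGLING_EDGE", str(exc)))
    return GraphStringOutcome(graph=graph, properties=properties)


def _assemble(
    name: str,
    nodes: list[tuple[str, str, Optional[float]]],
    edges: list[PolymerEdge],
    stat_paths: set[str],
) -> PolymerGraph:
    """Rebuild the container hierarchy from dotted node paths."""
    root = PolymerContainer(id=name, kind="linear")
    containers: dict[str, PolymerContainer] = {"": root}

    def get_container(path: str) -> PolymerContainer:
        if path in containers:
            return containers[path]
        parent_path, _, cid = path.rpartition(".")
        parent = get_container(parent_path)
        kind = "statistical" if path in stat_paths else "linear"
        sub = PolymerContainer(id=cid, kind=kind)
        parent.children.append(sub)
        containers[path] = sub
        return sub

    for stat in stat_paths:
        get_container(stat)
    for path, fragment, dp in nodes:
        parent_path, _, nid = path.rpartition(".")
        get_container(parent_path).children.append(PolymerNode(id=nid, fragment=fragment, dp=dp))

    # attach each edge to the deepest container containing both endpoints
    for edge in edges:
        src_parent = edge.source_path.rpartition(".")[0]
        tgt_parent = edge.target_path.rpartition(".")[0]
        common = _common_prefix(src_parent, tgt_parent)
        get_container(common).edges.append(edge)
    return build_graph(name, root)


def _common_prefix(a: str, b: str) -> str:
    pa = a.split(".") if a else []
    pb = b.split(".") if b else []
    out: list[str] = []
    for x, y in zip(pa, pb):
        if x != y:
            break
        out.append(x)
    return ".".join(out)


def canonical_graph_string(graph: PolymerGraph, strip_weights: bool = True) -> str:
    """Canonical string used for novelty/grouping: canonical fragment SMILES,
    weights (and dp annotations) stripped so only the structure is compared."""

    def strip_container(container: PolymerContainer) -> PolymerContainer:
        return PolymerContainer(
            id=container.id,
            kind=container.kind,
            children=[
                PolymerNode(id=c.id, fragment=canonical_fragment(c.fragment), dp=None)
                if isinstance(c, PolymerNode)
                else strip_container(c)
                for c in container.children
            ],
            edges=[
                replace(e, weight=None if strip_weights else e.weight) for e in container.edges
            ],
        )

    stripped = PolymerGraph(name=graph.name, root=strip_container(graph.root))
    return serialize_graph_string(stripped)


def graphs_equal(a: PolymerGraph, b: PolymerGraph, compare_weights: bool = True) -> bool:
    """Structural equality: same hierarchy, nodes, edges (and weights if asked)."""

    def norm(g: PolymerGraph) -> tuple:
        nodes = tuple(sorted((p, n.fragment, n.dp) for p, n in g.iter_nodes()))
        if compare_weights:
            # weights are printed with 4 decimals, so equality is at that precision
            edges = tuple(
                sorted(
                    (e.key(), e.quantity, None if e.weight is None else round(e.weight, 4))
                    for e in g.iter_edges()
                )
            )
        else:
            edges = tuple(sorted((e.key(), e.quantity) for e in g.iter_edges()))
        stats: list[str] = []

        def visit(c: PolymerContainer, prefix: str) -> None:
            for child in c.children:
                if isinstance(child, PolymerContainer):
                    if child.kind == "statistical":
                        stats.append(prefix + child.id)
                    visit(child, prefix + child.id + ".")

        visit(g.root, "")
        return (g.name, nodes, edges, tuple(sorted(stats)))

    return norm(a) == norm(b)

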