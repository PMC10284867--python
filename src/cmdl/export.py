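"""Export of interpreted records: JSON documents, ML training pairs, and
DP_n-binned Sankey aggregation of polymer-graph corpora.

The JSON export is the stable interchange form of a record — deterministic
key order, lossless re-import — and the aggregation utilities operate over
many such records to summarize which structural entities were combined at
which degrees of polymerization across a historical dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .flow import ReactorComponent, ReactorGraphSpec, StreamState
from .polymer import (
    PolymerContainer,
    PolymerEdge,
    PolymerGraph,
    PolymerNode,
    canonical_fragment,
)
from .records import (
    BatchReaction,
    ChemicalEntity,
    ExperimentRecord,
    FlowReaction,
    ResultMeasurement,
)
from .stoichiometry import StoichiometryRow, StoichiometryTable

__all__ = [
    "SCHEMA_VERSION",
    "export_json",
    "import_json",
    "TrainingPair",
    "to_training_pairs",
    "pairs_dataframe",
    "bin_dp",
    "bin_order",
    "SankeySummary",
    "build_sankey_summary",
]

SCHEMA_VERSION = 1
DEFAULT_BIN_EDGES = (25, 50, 100)


# ---------------------------------------------------------------------------
# JSON export / import
# ---------------------------------------------------------------------------


def _container_doc(container: PolymerContainer) -> dict:
    return {
        "id": container.id,
        "kind": container.kind,
        "children": [
            {"node": {"id": c.id, "fragment": c.fragment, "dp": c.dp}}
            if isinstance(c, PolymerNode)
            else {"container": _container_doc(c)}
            for c in container.children
        ],
        "edges": [
            {
                "source": f"{e.source_path}.{e.source_point}",
                "target": f"{e.target_path}.{e.target_point}",
                "quantity": e.quantity,
                "weight": e.weight,
            }
            for e in container.edges
        ],
    }


def _container_from_doc(doc: dict) -> PolymerContainer:
    children = []
    for entry in doc["children"]:
        if "node" in entry:
            n = entry["node"]
            children.append(PolymerNode(id=n["id"], fragment=n["fragment"], dp=n["dp"]))
        else:
            children.append(_container_from_doc(entry["container"]))
    edges = []
    for e in doc["edges"]:
        sp, _, sl = e["source"].rpartition(".")
        tp, _, tl = e["target"].rpartition(".")
        edges.append(
            PolymerEdge(
                source_path=sp,
                source_point=sl,
                target_path=tp,
                target_point=tl,
                quantity=e["quantity"],
                weight=e["weight"],
            )
        )
    return PolymerContainer(id=doc["id"], kind=doc["kind"], children=children, edges=edges)


def _table_doc(table: StoichiometryTable) -> dict:
    return {
        "reference": table.reference_entity,
        "total_volume_ml": table.total_volume_ml,
        "rows": [
            {
                "entity": r.entity.name,
                "moles": r.moles,
                "equivalents": r.equivalents,
                "mass_g": r.mass_g,
                "concentration_M": r.concentration_M,
            }
            for r in table.rows
        ],
    }


def _table_from_doc(doc: dict, chemicals: dict[str, ChemicalEntity]) -> StoichiometryTable:
    rows = [
        StoichiometryRow(
            entity=chemicals.get(r["entity"], ChemicalEntity(name=r["entity"])),
            moles=r["moles"],
            equivalents=r["equivalents"],
            mass_g=r["mass_g"],
            concentration_M=r["concentration_M"],
        )
        for r in doc["rows"]
    ]
    return StoichiometryTable(
        reference_entity=doc["reference"], rows=rows, total_volume_ml=doc["total_volume_ml"]
    )


def _record_doc(record: ExperimentRecord) -> dict:
    doc: dict = {"schemaVersion": SCHEMA_VERSION}
    doc["chemicals"] = {
        name: {
            "smiles": c.smiles,
            "molar_mass": c.molar_mass,
            "density": c.density,
            "state": c.state,
            "role": c.role,
        }
        for name, c in record.chemicals.items()
    }
    doc["polymers"] = {
        name: {"root": _container_doc(g.root)} for name, g in record.polymers.items()
    }
    doc["reactors"] = {
        name: {
            "components": [
                {"id": c.id, "kind": c.kind, "volume_ml": c.volume_ml} for c in spec.components
            ],
            "connections": [list(conn) for conn in spec.connections],
        }
        for name, spec in record.reactors.items()
    }
    reactions = []
    for rxn in record.reactions:
        if isinstance(rxn, BatchReaction):
            reactions.append(
                {
                    "type": "batch",
                    "name": rxn.name,
                    "table": _table_doc(rxn.table),
                    "temperature": rxn.temperature,
                    "time_min": rxn.time_min,
                }
            )
        else:
            reactions.append(
                {
                    "type": "flow",
                    "name": rxn.name,
                    "reactor": rxn.reactor,
                    "states": {
                        cid: {
                            "volumetric_flow_ml_min": s.volumetric_flow_ml_min,
                            "molar_flows": dict(sorted(s.molar_flows.items())),
                        }
                        for cid, s in sorted(rxn.states.items())
                    },
                    "residence_times_min": dict(sorted(rxn.residence_times_min.items())),
                    "table": None if rxn.table is None else _table_doc(rxn.table),
                }
            )
    doc["reactions"] = reactions
    doc["results"] = [
        {
            "name": r.name,
            "polymer": r.polymer,
            "conversion": r.conversion,
            "mn_gpc": r.mn_gpc,
            "dispersity": r.dispersity,
            "time_min": r.time_min,
            "dp_assignments": dict(sorted(r.dp_assignments.items())),
        }
        for r in record.results
    ]
    return doc


def export_json(record: ExperimentRecord) -> str:
    """Serialize a record to its canonical JSON text (deterministic key order)."""
    return json.dumps(_record_doc(record), sort_keys=True, indent=2)


def import_json(text: str) -> ExperimentRecord:
    """Inverse of :func:`export_json`; export(import(export(r))) is byte-identical."""
    doc = json.loads(text)
    if doc.get("schemaVersion") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {doc.get('schemaVersion')!r}")
    record = ExperimentRecord()
    for name, c in doc["chemicals"].items():
        record.chemicals[name] = ChemicalEntity(
            name=name,
            smiles=c["smiles"],
            molar_mass=c["molar_mass"],
            density=c["density"],
            state=c["state"],
            role=c["role"],
        )
    for name, p in doc["polymers"].items():
        record.polymers[name] = PolymerGraph(name=name, root=_container_from_doc(p["root"]))
    for name, r in doc["reactors"].items():
        record.reactors[name] = ReactorGraphSpec(
            name=name,
            components=[
                ReactorComponent(id=c["id"], kind=c["kind"], volume_ml=c["volume_ml"])
                for c in r["components"]
            ],
            connections=[tuple(conn) for conn in r["connections"]],
        )
    for rxn in doc["reactions"]:
        if rxn["type"] == "batch":
            record.reactions.append(
                BatchReaction(
                    name=rxn["name"],
                    table=_table_from_doc(rxn["table"], record.chemicals),
                    temperature=rxn["temperature"],
                    time_min=rxn["time_min"],
                )
            )
        else:
            states = {
                cid: StreamState(
                    component_id=cid,
                    volumetric_flow_ml_min=s["volumetric_flow_ml_min"],
                    molar_flows=s["molar_flows"],
                )
                for cid, s in rxn["states"].items()
            }
            record.reactions.append(
                FlowReaction(
                    name=rxn["name"],
                    reactor=rxn["reactor"],
                    states=states,
                    residence_times_min=rxn["residence_times_min"],
                    table=None
                    if rxn["table"] is None
                    else _table_from_doc(rxn["table"], record.chemicals),
                )
            )
    for r in doc["results"]:
        record.results.append(
            ResultMeasurement(
                name=r["name"],
                polymer=r["polymer"],
                conversion=r["conversion"],
                mn_gpc=r["mn_gpc"],
                dispersity=r["dispersity"],
                time_min=r["time_min"],
                dp_assignments=r["dp_assignments"],
            )
        )
    return record


# ---------------------------------------------------------------------------
# training pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingPair:
    """One supervised example: a monomer-catalyst pair with its outcomes."""

    monomer_smiles: str
    catalyst_smiles: str
    conversion: float
    dispersity: float
    log10_mn: float


def to_training_pairs(
    records: Iterable[ExperimentRecord],
) -> tuple[list[TrainingPair], int]:
    """Flatten records into (monomer, catalyst, result) training rows.

    M_n is transformed to log10(g/mol).  Rows missing a monomer, catalyst, or
    any of the three properties are dropped; the second return value counts
    the drops.
    """
    pairs: list[TrainingPair] = []
    dropped = 0
    for record in records:
        monomers = [c for c in record.chemicals.values() if c.role == "monomer" and c.smiles]
        catalysts = [c for c in record.chemicals.values() if c.role == "catalyst" and c.smiles]
        for result in record.results:
            if (
                not monomers
                or not catalysts
                or result.conversion is None
                or result.dispersity is None
                or result.mn_gpc is None
            ):
                dropped += 1
                continue
            for monomer in monomers:
                for catalyst in catalysts:
                    pairs.append(
                        TrainingPair(
                            monomer_smiles=monomer.smiles,
                            catalyst_smiles=catalyst.smiles,
                            conversion=result.conversion,
                            dispersity=result.dispersity,
                            log10_mn=math.log10(result.mn_gpc),
                        )
                    )
    return pairs, dropped


def pairs_dataframe(pairs: list[TrainingPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "monomer_smiles": p.monomer_smiles,
                "catalyst_smiles": p.catalyst_smiles,
                "conversion": p.conversion,
                "dispersity": p.dispersity,
                "log10_mn": p.log10_mn,
            }
            for p in pairs
        ],
        columns=["monomer_smiles", "catalyst_smiles", "conversion", "dispersity", "log10_mn"],
    )


# ---------------------------------------------------------------------------
# DP_n binning and Sankey aggregation
# ---------------------------------------------------------------------------


def bin_dp(dp: float, bin_edges: Iterable[float] = DEFAULT_BIN_EDGES) -> str:
    """Bin label for an assigned DP_n.

    0 labels a failed polymerization; otherwise half-open bins (lo, hi]
    labeled by their upper edge; values beyond the last edge get ``>last``.
    """
    if dp < 0:
        raise ValueError(f"DP_n must be >= 0, got {dp}")
    edges = sorted(bin_edges)
    if not edges:
        raise ValueError("need at least one bin edge")
    if dp == 0:
        return "0"
    for hi in edges:
        if dp <= hi:
            return _fmt_edge(hi)
    return f">{_fmt_edge(edges[-1])}"


def _fmt_edge(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def bin_order(label: str, bin_edges: Iterable[float] = DEFAULT_BIN_EDGES) -> int:
    """Rank of a bin label, for monotonicity checks and sorted output."""
    edges = sorted(bin_edges)
    ordering = ["0"] + [_fmt_edge(e) for e in edges] + [f">{_fmt_edge(edges[-1])}"]
    return ordering.index(label)


@dataclass
class SankeySummary:
    """Aggregated node/link counts over a corpus of polymer graphs."""

    nodes: list[str] = field(default_factory=list)
    links: list[tuple[str, str, int]] = field(default_factory=list)  # (source, target, count)

    def as_dict(self) -> dict:
        return {
            "nodes": [{"id": n} for n in self.nodes],
            "links": [{"source": s, "target": t, "value": c} for s, t, c in self.links],
        }


def _node_label(
    graph: PolymerGraph,
    path: str,
    node: PolymerNode,
    repeat_paths: set[str],
    labels: dict[str, str],
    bin_edges: Iterable[float],
) -> str:
    """Label = entity name + DP_n-bin suffix (repeat units only).

    Entity identity is the canonical wildcard-SMILES of the fragment so that
    the same repeat unit declared in different records merges; the display
    name is the lexicographically smallest node id seen for that fragment.
    """
    key = canonical_fragment(node.fragment)
    name = labels.setdefault(key, node.id)
    if node.id < name:
        labels[key] = name = node.id
    if path in repeat_paths and node.dp is not None:
        return f"{name}-{bin_dp(node.dp, bin_edges)}"
    return name


def build_sankey_summary(
    graphs: Iterable[PolymerGraph],
    bin_edges: Iterable[float] = DEFAULT_BIN_EDGES,
) -> SankeySummary:
    """Group a corpus of weighted polymer graphs into a Sankey node/link table.

    A link (A, B) counts the number of input graphs containing an edge between
    entity A and entity B at those DP_n bins; self-edges define repeat-unit
    status but do not produce links.
    """
    from .polymer import _repeat_paths  # internal reuse

    graphs = list(graphs)
    display: dict[str, str] = {}
    # first pass fixes display names so labels are input-order invariant
    for graph in graphs:
        for _, node in sorted(graph.iter_nodes(), key=lambda kv: kv[1].id):
            key = canonical_fragment(node.fragment)
            if key not in display or node.id < display[key]:
                display[key] = node.id

    link_counts: dict[tuple[str, str], int] = {}
    node_labels: set[str] = set()
    for graph in graphs:
        repeats = _repeat_paths(graph)
        path_labels = {
            path: _node_label(graph, path, node, repeats, display, bin_edges)
            for path, node in graph.iter_nodes()
        }
        node_labels.update(path_labels.values())
        seen_links: set[tuple[str, str]] = set()
        for edge in graph.iter_edges():
            if edge.is_self_edge:
                continue
            link = (path_labels[edge.source_path], path_labels[edge.target_path])
            if link not in seen_links:
                seen_links.add(link)
                link_counts[link] = link_counts.get(link, 0) + 1
    return SankeySummary(
        nodes=sorted(node_labels),
        links=[(s, t, c) for (s, t), c in sorted(link_counts.items())],
    )
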