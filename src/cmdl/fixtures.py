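"""Programmatic CMDL fixture records: every architecture and experiment type.

Everything the test suite and the worked examples consume is generated here,
from real ring-opening-polymerization chemistry: lactone/cyclic-carbonate
monomers, alcohol initiators, amidine/guanidine organocatalysts.  Identical
:class:`FixtureSpec` inputs (including the seed) yield byte-identical text.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FixtureSpec",
    "make_record",
    "make_dataset",
    "make_random_reactor",
    "CHEMICALS",
    "FRAGMENTS",
    "KINDS",
]

KINDS = (
    "homopolymer",
    "diol_telechelic",
    "graft",
    "dendrimer",
    "block_copolymer",
    "statistical_copolymer",
    "batch_rop",
    "flow_rop",
)

# name -> (smiles, molar mass g/mol, state, role)
CHEMICALS: dict[str, tuple[str, float, str, str]] = {
    "mba": ("Cc1ccc(CO)cc1", 122.17, "solid", "initiator"),  # 4-methylbenzyl alcohol
    "pyrenebutanol": ("OCCCCc1ccc2ccc3cccc4ccc1c2c34", 274.36, "solid", "initiator"),
    "dbu": ("C1CCC2=NCCCN2CC1", 152.24, "liquid", "catalyst"),
    "tbd": ("C1CC2=NCCCN2CN1", 139.20, "solid", "catalyst"),
    "guanidine_acyclic": ("CN(C)C(=NC(C)(C)C)N(C)C", 171.29, "liquid", "catalyst"),
    "valerolactone": ("O=C1CCCCO1", 100.12, "liquid", "monomer"),
    "lactide": ("CC1OC(=O)C(C)OC1=O", 144.13, "solid", "monomer"),
    "tmc": ("O=C1OCCCO1", 102.09, "solid", "monomer"),
    "mtc_obn": ("O=C1OCC(C)(C(=O)OCc2ccccc2)CO1", 250.25, "solid", "monomer"),
    "dcm": ("ClCCl", 84.93, "liquid", "solvent"),
    "benzoic_acid": ("OC(=O)c1ccccc1", 122.12, "solid", "quench"),
}

# g/mL, for reagents dispensed by volume
DENSITIES: dict[str, float] = {
    "dcm": 1.325,
    "dbu": 1.018,
    "valerolactone": 1.079,
    "guanidine_acyclic": 0.918,
}

# SMILES fragments with attachment-point placeholders, per repeat unit
FRAGMENTS: dict[str, str] = {
    "pyrenebutanol_end": "[R]OCCCCc1ccc2ccc3cccc4ccc1c2c34",
    "mba_end": "[R]OCc1ccc(C)cc1",
    "valerolactone_repeat": "[R]C(=O)CCCCO[Q]",
    "lactide_repeat": "[R]C(=O)C(C)OC(=O)C(C)O[Q]",
    "tmc_repeat": "[R]C(=O)OCCCO[Q]",
    "mtc_obn_repeat": "[R]C(=O)OCC(C)(C(=O)OCc1ccccc1)CO[Q]",
    "butanediol_core": "[R]OCCCCO[R]",  # symmetric diol: both points share one letter
    "trimethylolpropane_core": "CCC(CO[R])(CO[R])CO[R]",  # 3-arm dendritic core
    "pentaerythritol_core": "C(CO[R])(CO[R])(CO[R])CO[R]",  # 4-arm dendritic core
    "graft_backbone": "[R]C(=O)OCC(CO[X])(C)CO[Q]",  # carbonate backbone with graft site
}

_REPEAT_FOR_MONOMER = {
    "valerolactone": "valerolactone_repeat",
    "lactide": "lactide_repeat",
    "tmc": "tmc_repeat",
    "mtc_obn": "mtc_obn_repeat",
}

_CORE_FOR_ARMS = {3: "trimethylolpropane_core", 4: "pentaerythritol_core"}


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; expected one of {KINDS}")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def _chemical_block(name: str) -> str:
    smiles, mm, state, role = CHEMICALS[name]
    density = f"    density: {_fmt(DENSITIES[name])} g/mL;\n" if name in DENSITIES else ""
    return (
        f"chemical {name} {{\n"
        f'    smiles: "{smiles}";\n'
        f"    molar_mass: {_fmt(mm)} g/mol;\n"
        f"{density}"
        f"    state: {state};\n"
        f"    role: {role};\n"
        f"}}"
    )


def _homopolymer_graph(
    name: str, end_fragment: str, repeat_fragment: str, dp: float
) -> str:
    return (
        f"polymer_graph {name} {{\n"
        f"    node end_group {{\n"
        f'        fragment: "{end_fragment}";\n'
        f"    }}\n"
        f"    node repeat {{\n"
        f'        fragment: "{repeat_fragment}";\n'
        f"        dp: {_fmt(dp)};\n"
        f"    }}\n"
        f"    edge {{ source: @end_group.R; target: @repeat.Q; }}\n"
        f"    edge {{ source: @repeat.R; target: @repeat.Q; }}\n"
        f"}}"
    )


def make_record(spec: FixtureSpec) -> str:
    """Emit the CMDL text for one fixture record; compiles with no errors."""
    p = dict(spec.parameters)
    kind = spec.kind
    if kind == "homopolymer":
        dp = p.get("dp", 50)
        monomer = p.get("monomer", "valerolactone")
        return "\n\n".join(
            [
                _homopolymer_graph(
                    p.get("name", "pvl"),
                    FRAGMENTS[p.get("end_fragment", "pyrenebutanol_end")],
                    FRAGMENTS[_REPEAT_FOR_MONOMER[monomer]],
                    dp,
                )
            ]
        ) + "\n"
    if kind == "diol_telechelic":
        dp = p.get("dp", 50)
        q = 2
        monomer = p.get("monomer", "valerolactone")
        repeat = FRAGMENTS[_REPEAT_FOR_MONOMER[monomer]]
        if p.get("expanded", False):
            edges = "\n".join(
                f"    edge {{ source: @core.R; target: @arm{i}.Q; }}\n"
                f"    edge {{ source: @arm{i}.R; target: @arm{i}.Q; }}"
                for i in range(1, q + 1)
            )
            arms = "\n".join(
                f"    node arm{i} {{\n"
                f'        fragment: "{repeat}";\n'
                f"        dp: {_fmt(dp)};\n"
                f"    }}"
                for i in range(1, q + 1)
            )
            body = (
                f"    node core {{\n"
                f'        fragment: "{FRAGMENTS["butanediol_core"]}";\n'
                f"    }}\n{arms}\n{edges}"
            )
        else:
            body = (
                f"    node core {{\n"
                f'        fragment: "{FRAGMENTS["butanediol_core"]}";\n'
                f"    }}\n"
                f"    node arm {{\n"
                f'        fragment: "{repeat}";\n'
                f"        dp: {_fmt(dp)};\n"
                f"    }}\n"
                f"    edge {{ source: @core.R; target: @arm.Q; quantity: 2; }}\n"
                f"    edge {{ source: @arm.R; target: @arm.Q; quantity: 2; }}"
            )
        return f"polymer_graph {p.get('name', 'telechelic')} {{\n{body}\n}}\n"
    if kind == "dendrimer":
        dp = p.get("dp", 25)
        q = p.get("q", 4)
        core = FRAGMENTS[_CORE_FOR_ARMS[q]]
        monomer = p.get("monomer", "valerolactone")
        repeat = FRAGMENTS[_REPEAT_FOR_MONOMER[monomer]]
        if p.get("expanded", False):
            arms = "\n".join(
                f"    node arm{i} {{\n"
                f'        fragment: "{repeat}";\n'
                f"        dp: {_fmt(dp)};\n"
                f"    }}"
                for i in range(1, q + 1)
            )
            edges = "\n".join(
                f"    edge {{ source: @core.R; target: @arm{i}.Q; }}\n"
                f"    edge {{ source: @arm{i}.R; target: @arm{i}.Q; }}"
                for i in range(1, q + 1)
            )
            body = f'    node core {{\n        fragment: "{core}";\n    }}\n{arms}\n{edges}'
        else:
            body = (
                f"    node core {{\n"
                f'        fragment: "{core}";\n'
                f"    }}\n"
                f"    node arm {{\n"
                f'        fragment: "{repeat}";\n'
                f"        dp: {_fmt(dp)};\n"
                f"    }}\n"
                f"    edge {{ source: @core.R; target: @arm.Q; quantity: {q}; }}\n"
                f"    edge {{ source: @arm.R; target: @arm.Q; quantity: {q}; }}"
            )
        return f"polymer_graph {p.get('name', 'star')} {{\n{body}\n}}\n"
    if kind == "graft":
        dp_backbone = p.get("dp_backbone", 20)
        dp_side = p.get("dp_side", 10)
        return (
            f"polymer_graph {p.get('name', 'graft')} {{\n"
            f"    node end_group {{\n"
            f'        fragment: "{FRAGMENTS["mba_end"]}";\n'
            f"    }}\n"
            f"    node backbone {{\n"
            f'        fragment: "{FRAGMENTS["graft_backbone"]}";\n'
            f"        dp: {_fmt(dp_backbone)};\n"
            f"    }}\n"
            f"    container side {{\n"
            f"        kind: linear;\n"
            f"        node sidechain {{\n"
            f'            fragment: "{FRAGMENTS["valerolactone_repeat"]}";\n'
            f"            dp: {_fmt(dp_side)};\n"
            f"        }}\n"
            f"        edge {{ source: @sidechain.R; target: @sidechain.Q; }}\n"
            f"    }}\n"
            f"    edge {{ source: @end_group.R; target: @backbone.Q; }}\n"
            f"    edge {{ source: @backbone.R; target: @backbone.Q; }}\n"
            f"    edge {{ source: @backbone.X; target: @side.sidechain.Q; }}\n"
            f"}}\n"
        )
    if kind in ("block_copolymer", "statistical_copolymer"):
        dp_a = p.get("dp_a", 30)
        dp_b = p.get("dp_b", 20)
        mon_a = p.get("monomer_a", "tmc")
        mon_b = p.get("monomer_b", "mtc_obn")
        frag_a = FRAGMENTS[_REPEAT_FOR_MONOMER[mon_a]]
        frag_b = FRAGMENTS[_REPEAT_FOR_MONOMER[mon_b]]
        end = FRAGMENTS[p.get("end_fragment", "pyrenebutanol_end")]
        if kind == "block_copolymer":
            return (
                f"polymer_graph {p.get('name', 'block')} {{\n"
                f'    node end_group {{\n        fragment: "{end}";\n    }}\n'
                f'    node block_a {{\n        fragment: "{frag_a}";\n        dp: {_fmt(dp_a)};\n    }}\n'
                f'    node block_b {{\n        fragment: "{frag_b}";\n        dp: {_fmt(dp_b)};\n    }}\n'
                f"    edge {{ source: @end_group.R; target: @block_a.Q; }}\n"
                f"    edge {{ source: @block_a.R; target: @block_a.Q; }}\n"
                f"    edge {{ source: @block_a.R; target: @block_b.Q; }}\n"
                f"    edge {{ source: @block_b.R; target: @block_b.Q; }}\n"
                f"}}\n"
            )
        return (
            f"polymer_graph {p.get('name', 'statistical')} {{\n"
            f'    node end_group {{\n        fragment: "{end}";\n    }}\n'
            f"    container stat {{\n"
            f"        kind: statistical;\n"
            f'        node unit_a {{\n            fragment: "{frag_a}";\n            dp: {_fmt(dp_a)};\n        }}\n'
            f'        node unit_b {{\n            fragment: "{frag_b}";\n            dp: {_fmt(dp_b)};\n        }}\n'
            f"        edge {{ source: @unit_a.R; target: @unit_a.Q; }}\n"
            f"        edge {{ source: @unit_a.R; target: @unit_b.Q; }}\n"
            f"        edge {{ source: @unit_b.R; target: @unit_b.Q; }}\n"
            f"    }}\n"
            f"    edge {{ source: @end_group.R; target: @stat.unit_a.Q; }}\n"
            f"}}\n"
        )
    if kind == "batch_rop":
        return _batch_rop_record(p)
    if kind == "flow_rop":
        return _flow_rop_record(p)
    raise ValueError(f"unknown fixture kind {kind!r}")  # pragma: no cover


def _batch_rop_record(p: dict) -> str:
    """A complete batch ROP record: reagents, polymer graph, measured result.

    Default masses follow the bench convention of a 0.04 mmol initiator
    charge with catalyst at 2.5 eq and monomer at the targeted DP_n.
    """
    monomer = p.get("monomer", "valerolactone")
    catalyst = p.get("catalyst", "dbu")
    initiator = p.get("initiator", "mba")
    architecture = p.get("architecture", "homopolymer")
    dp = p.get("dp", 50)
    init_mmol = p.get("initiator_mmol", 0.04)
    init_mass = init_mmol * CHEMICALS[initiator][1]  # mg per mmol = g/mol
    cat_mass = p.get("catalyst_eq", 2.5) * init_mmol * CHEMICALS[catalyst][1]
    mon_mass = dp * init_mmol * CHEMICALS[monomer][1]
    conversion = p.get("conversion", 0.98)
    dispersity = p.get("dispersity", 1.12)
    dp_measured = p.get("dp_measured", dp * conversion)
    mn = p.get(
        "mn_gpc",
        max(dp_measured * CHEMICALS[monomer][1], 1.0) + CHEMICALS[initiator][1],
    )
    if architecture == "homopolymer":
        end_fragment = "mba_end" if initiator == "mba" else "pyrenebutanol_end"
        graph_text = _homopolymer_graph(
            "product", FRAGMENTS[end_fragment], FRAGMENTS[_REPEAT_FOR_MONOMER[monomer]], dp
        )
        repeat_path = "repeat"
    else:
        graph_text = make_record(
            FixtureSpec(
                kind=architecture,
                parameters={"name": "product", "monomer": monomer, "dp": dp},
            )
        ).rstrip("\n")
        repeat_path = "arm"
    blocks = [_chemical_block(n) for n in (initiator, catalyst, monomer, "dcm")]
    blocks.append(graph_text)
    blocks.append(
        f"reaction polymerization {{\n"
        f"    time: {_fmt(p.get('time_min', 30))} min;\n"
        f"    reagent {{ entity: @{initiator}; mass: {_fmt(round(init_mass, 4))} mg; reference: true; }}\n"
        f"    reagent {{ entity: @{catalyst}; mass: {_fmt(round(cat_mass, 4))} mg; }}\n"
        f"    reagent {{ entity: @{monomer}; mass: {_fmt(round(mon_mass, 4))} mg; }}\n"
        f"    reagent {{ entity: @dcm; volume: 1 mL; }}\n"
        f"}}"
    )
    blocks.append(
        f"result analysis {{\n"
        f"    polymer: @product;\n"
        f"    conversion: {_fmt(conversion)};\n"
        f"    mn_gpc: {_fmt(mn)} g/mol;\n"
        f"    dispersity: {_fmt(dispersity)};\n"
        f"    time: {_fmt(p.get('time_min', 30))} min;\n"
        f"    dp {{ node: @product.{repeat_path}; value: {_fmt(dp_measured)}; }}\n"
        f"}}"
    )
    return "\n\n".join(blocks) + "\n"


def _flow_rop_record(p: dict) -> str:
    """Two reactors in series with monomer, catalyst and quench syringes;
    the quench stream joins only after the first reactor."""
    monomer_rate = p.get("monomer_rate", 0.5)
    catalyst_rate = p.get("catalyst_rate", 0.25)
    quench_rate = p.get("quench_rate", 0.75)
    va = p.get("reactor_a_volume", 0.5)
    vb = p.get("reactor_b_volume", 0.3)
    monomer_conc = p.get("monomer_conc", 2.0)
    catalyst_conc = p.get("catalyst_conc", 0.08)
    initiator_conc = p.get("initiator_conc", 0.04)
    quench_conc = p.get("quench_conc", 0.5)
    blocks = [
        _chemical_block(n)
        for n in ("pyrenebutanol", "dbu", "valerolactone", "benzoic_acid")
    ]
    blocks.append(
        "reactor_graph rig {\n"
        "    component monomer_syringe { kind: input; }\n"
        "    component catalyst_syringe { kind: input; }\n"
        "    component quench_syringe { kind: input; }\n"
        "    component mixer_a { kind: mixer; }\n"
        f"    component reactor_a {{ kind: reactor; volume: {_fmt(va)} mL; }}\n"
        "    component mixer_b { kind: mixer; }\n"
        f"    component reactor_b {{ kind: reactor; volume: {_fmt(vb)} mL; }}\n"
        "    component collection { kind: collection; }\n"
        "    connect { from: @monomer_syringe; to: @mixer_a; }\n"
        "    connect { from: @catalyst_syringe; to: @mixer_a; }\n"
        "    connect { from: @mixer_a; to: @reactor_a; }\n"
        "    connect { from: @reactor_a; to: @mixer_b; }\n"
        "    connect { from: @quench_syringe; to: @mixer_b; }\n"
        "    connect { from: @mixer_b; to: @reactor_b; }\n"
        "    connect { from: @reactor_b; to: @collection; }\n"
        "}"
    )
    blocks.append(
        "flow_reaction run {\n"
        "    reactor: @rig;\n"
        "    input {\n"
        "        component: @rig.monomer_syringe;\n"
        f"        flow_rate: {_fmt(monomer_rate)} mL/min;\n"
        f"        solution {{ entity: @valerolactone; concentration: {_fmt(monomer_conc)} mol/L; }}\n"
        "    }\n"
        "    input {\n"
        "        component: @rig.catalyst_syringe;\n"
        f"        flow_rate: {_fmt(catalyst_rate)} mL/min;\n"
        f"        solution {{ entity: @dbu; concentration: {_fmt(catalyst_conc)} mol/L; }}\n"
        f"        solution {{ entity: @pyrenebutanol; concentration: {_fmt(initiator_conc)} mol/L; }}\n"
        "    }\n"
        "    input {\n"
        "        component: @rig.quench_syringe;\n"
        f"        flow_rate: {_fmt(quench_rate)} mL/min;\n"
        f"        solution {{ entity: @benzoic_acid; concentration: {_fmt(quench_conc)} mol/L; }}\n"
        "    }\n"
        "}"
    )
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# random reactor graphs (for conservation checks)
# ---------------------------------------------------------------------------


def make_random_reactor(seed: int):
    """A random valid flow-reactor DAG plus a complete feed assignment.

    Between 1 and 4 syringe inputs feed a random series/parallel arrangement
    of mixers and reactor coils that drains into a single collection vessel.
    Returns ``(ReactorGraphSpec, dict[input id, InputFeed])``.
    """
    from .flow import InputFeed, ReactorComponent, ReactorGraphSpec

    rng = random.Random(seed)
    n_inputs = rng.randint(1, 4)
    n_middle = rng.randint(1, 6)
    components = [ReactorComponent(id=f"in{i}", kind="input") for i in range(n_inputs)]
    middle_ids = []
    for i in range(n_middle):
        if rng.random() < 0.5:
            components.append(
                ReactorComponent(
                    id=f"r{i}", kind="reactor", volume_ml=round(rng.uniform(0.1, 2.0), 3)
                )
            )
        else:
            components.append(ReactorComponent(id=f"m{i}", kind="mixer"))
        middle_ids.append(components[-1].id)
    components.append(ReactorComponent(id="collect", kind="collection"))

    connections: list[tuple[str, str]] = []
    # each input feeds a random middle node; each middle node feeds a later
    # middle node or the collection, which keeps the graph acyclic
    for i in range(n_inputs):
        connections.append((f"in{i}", rng.choice(middle_ids)))
    for i, mid in enumerate(middle_ids):
        later = middle_ids[i + 1 :] + ["collect"]
        first = rng.choice(later)
        connections.append((mid, first))
        remaining = [t for t in later if t != first]
        if remaining and rng.random() < 0.3:  # occasional split
            connections.append((mid, rng.choice(remaining)))
    spec = ReactorGraphSpec(name=f"random_{seed}", components=components, connections=connections)

    # drop components no input reaches (they would have zero flow anyway)
    g = spec.digraph()
    import networkx as nx

    reachable = set()
    for i in range(n_inputs):
        reachable |= {f"in{i}"} | nx.descendants(g, f"in{i}")
    spec = ReactorGraphSpec(
        name=spec.name,
        components=[c for c in components if c.id in reachable],
        connections=[(a, b) for a, b in connections if a in reachable and b in reachable],
    )

    entities = ["monomer", "catalyst", "initiator", "quench"]
    assignment = {
        f"in{i}": InputFeed(
            flow_ml_min=round(rng.uniform(0.05, 2.0), 4),
            solution=((entities[i % len(entities)], round(rng.uniform(0.01, 2.0), 4)),),
        )
        for i in range(n_inputs)
    }
    return spec, assignment


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_DATASET_MONOMERS = ("valerolactone", "lactide", "tmc", "mtc_obn")
_DATASET_CATALYSTS = ("dbu", "tbd", "guanidine_acyclic")
# single-monomer architectures, so each record yields exactly one training pair
_DATASET_ARCHITECTURES = (("homopolymer", 0.6), ("diol_telechelic", 0.25), ("dendrimer", 0.15))
_DATASET_DP_CHOICES = (25, 50, 100)
_FAILURE_RATE = 0.05  # fraction of reactions recorded as failed (DP_n = 0)


def make_dataset(n: int, seed: int) -> tuple[list[str], pd.DataFrame]:
    """Sample ``n`` complete batch-ROP records plus their ground-truth table.

    Sampling order per record (fixed for reproducibility): monomer, catalyst,
    architecture, target DP_n, failure flag, conversion, dispersity.
    Dispersity is 1 + |N(0, 0.1)|; conversion is uniform on [0.85, 1] for
    successful reactions and 0 for failures (which carry DP_n = 0).
    """
    rng = random.Random(seed)
    records: list[str] = []
    truth_rows: list[dict] = []
    arch_names = [a for a, _ in _DATASET_ARCHITECTURES]
    arch_weights = [w for _, w in _DATASET_ARCHITECTURES]
    for i in range(n):
        monomer = rng.choice(_DATASET_MONOMERS)
        catalyst = rng.choice(_DATASET_CATALYSTS)
        architecture = rng.choices(arch_names, weights=arch_weights, k=1)[0]
        dp_target = rng.choice(_DATASET_DP_CHOICES)
        failed = rng.random() < _FAILURE_RATE
        conversion = 0.0 if failed else rng.uniform(0.85, 1.0)
        dispersity = 1.0 + abs(rng.gauss(0.0, 0.1))
        dp_measured = 0.0 if failed else dp_target * conversion
        mn = max(dp_measured * CHEMICALS[monomer][1], 1.0) + CHEMICALS["mba"][1]
        params = {
            "monomer": monomer,
            "catalyst": catalyst,
            "architecture": architecture,
            "dp": dp_target,
            "conversion": conversion,
            "dispersity": dispersity,
            "dp_measured": dp_measured,
            "mn_gpc": mn,
        }
        records.append(make_record(FixtureSpec(kind="batch_rop", parameters=params, seed=seed)))
        truth_rows.append(
            {
                "record": i,
                "monomer": monomer,
                "monomer_smiles": CHEMICALS[monomer][0],
                "catalyst": catalyst,
                "catalyst_smiles": CHEMICALS[catalyst][0],
                "architecture": architecture,
                "dp_target": dp_target,
                "dp_measured": dp_measured,
                "failed": failed,
                "conversion": conversion,
                "dispersity": dispersity,
                "mn_gpc": mn,
                "log10_mn": math.log10(mn),
            }
        )
    columns = [
        "record",
        "monomer",
        "monomer_smiles",
        "catalyst",
        "catalyst_smiles",
        "architecture",
        "dp_target",
        "dp_measured",
        "failed",
        "conversion",
        "dispersity",
        "mn_gpc",
        "log10_mn",
    ]
    return records, pd.DataFrame(truth_rows, columns=columns)
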