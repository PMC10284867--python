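"""Flow reactors: graph validation, flow propagation, residence times, Sankey."""

from __future__ import annotations

import random

import pytest

from cmdl.fixtures import FixtureSpec, make_random_reactor, make_record
from cmdl.flow import (
    FlowError,
    InputFeed,
    ReactorComponent,
    ReactorGraphSpec,
    flow_stoichiometry,
    propagate_flows,
    residence_time,
    sankey_export,
    validate_reactor_graph,
)
from cmdl.interpreter import compile_text
from cmdl.records import FlowReaction
from cmdl.stoichiometry import StoichiometryError


def chain_spec() -> ReactorGraphSpec:
    return ReactorGraphSpec(
        name="chain",
        components=[
            ReactorComponent("feed", "input"),
            ReactorComponent("coil", "reactor", volume_ml=2.0),
            ReactorComponent("vial", "collection"),
        ],
        connections=[("feed", "coil"), ("coil", "vial")],
    )


def two_reactor_spec() -> ReactorGraphSpec:
    """The mid-stream-input shape: two reactors in series, quench joins late."""
    return ReactorGraphSpec(
        name="series",
        components=[
            ReactorComponent("monomer", "input"),
            ReactorComponent("catalyst", "input"),
            ReactorComponent("quench", "input"),
            ReactorComponent("mix_a", "mixer"),
            ReactorComponent("reactor_a", "reactor", volume_ml=0.3),
            ReactorComponent("mix_b", "mixer"),
            ReactorComponent("reactor_b", "reactor", volume_ml=0.5),
            ReactorComponent("vial", "collection"),
        ],
        connections=[
            ("monomer", "mix_a"),
            ("catalyst", "mix_a"),
            ("mix_a", "reactor_a"),
            ("reactor_a", "mix_b"),
            ("quench", "mix_b"),
            ("mix_b", "reactor_b"),
            ("reactor_b", "vial"),
        ],
    )


class TestValidate:
    def test_simple_chain_is_clean(self):
        assert validate_reactor_graph(chain_spec()) == []

    def test_two_reactor_series_is_clean(self):
        assert validate_reactor_graph(two_reactor_spec()) == []

    def test_collection_outflow_flagged(self):
        spec = chain_spec()
        spec.connections.append(("vial", "coil"))
        codes = {d.code for d in validate_reactor_graph(spec)}
        assert "SINK_OUTFLOW" in codes

    def test_cycle_flagged(self):
        spec = ReactorGraphSpec(
            name="loop",
            components=[
                ReactorComponent("feed", "input"),
                ReactorComponent("a", "mixer"),
                ReactorComponent("b", "mixer"),
                ReactorComponent("vial", "collection"),
            ],
            connections=[("feed", "a"), ("a", "b"), ("b", "a"), ("b", "vial")],
        )
        codes = {d.code for d in validate_reactor_graph(spec)}
        assert "CYCLE" in codes

    def test_orphan_component_flagged(self):
        spec = chain_spec()
        spec.components.append(ReactorComponent("stray", "mixer"))
        codes = {d.code for d in validate_reactor_graph(spec)}
        assert "UNREACHABLE" in codes

    def test_reactor_without_volume_flagged(self):
        spec = chain_spec()
        spec.components[1] = ReactorComponent("coil", "reactor", volume_ml=None)
        codes = {d.code for d in validate_reactor_graph(spec)}
        assert "BAD_VOLUME" in codes


class TestPropagate:
    def test_merging_streams_adds_volumetric_flows(self):
        spec = two_reactor_spec()
        states = propagate_flows(
            spec,
            {
                "monomer": InputFeed(0.5),
                "catalyst": InputFeed(0.25),
                "quench": InputFeed(0.0),
            },
        )
        assert states["mix_a"].volumetric_flow_ml_min == pytest.approx(0.75)

    def test_molar_flow_from_concentration(self):
        states = propagate_flows(
            chain_spec(), {"feed": InputFeed(1.0, (("monomer", 0.1),))}
        )
        assert states["vial"].molar_flows["monomer"] == pytest.approx(1e-4)

    def test_three_syringe_fixture_by_hand(self):
        """Quench joins only after reactor A; every stream sums by hand."""
        spec = two_reactor_spec()
        states = propagate_flows(
            spec,
            {
                "monomer": InputFeed(0.5, (("vl", 2.0),)),
                "catalyst": InputFeed(0.25, (("dbu", 0.08),)),
                "quench": InputFeed(0.75, (("acid", 0.5),)),
            },
        )
        assert states["reactor_a"].volumetric_flow_ml_min == pytest.approx(0.75)
        assert "acid" not in states["reactor_a"].molar_flows
        assert states["reactor_b"].volumetric_flow_ml_min == pytest.approx(1.5)
        assert states["vial"].molar_flows["vl"] == pytest.approx(0.5 * 2.0 / 1000)
        assert states["vial"].molar_flows["acid"] == pytest.approx(0.75 * 0.5 / 1000)

    @pytest.mark.parametrize("seed", range(40))
    def test_conservation_on_random_dags(self, seed):
        """Inflow equals outflow at every non-input node, to 1e-12 relative."""
        spec, assignment = make_random_reactor(seed)
        assert validate_reactor_graph(spec) == []
        states = propagate_flows(spec, assignment)
        g = spec.digraph()
        for c in spec.components:
            if c.kind == "input":
                continue
            inflow = sum(
                states[p].volumetric_flow_ml_min / g.out_degree(p) for p in g.predecessors(c.id)
            )
            flow = states[c.id].volumetric_flow_ml_min
            assert abs(inflow - flow) <= 1e-12 * max(flow, 1.0)
            for entity, mf in states[c.id].molar_flows.items():
                in_mf = sum(
                    states[p].molar_flows.get(entity, 0.0) / g.out_degree(p)
                    for p in g.predecessors(c.id)
                )
                assert abs(in_mf - mf) <= 1e-12 * max(mf, 1.0)

    def test_order_independence(self):
        """Shuffling declaration order never changes the propagated states."""
        spec, assignment = make_random_reactor(7)
        baseline = propagate_flows(spec, assignment)
        rng = random.Random(0)
        for _ in range(5):
            components = spec.components[:]
            connections = spec.connections[:]
            rng.shuffle(components)
            rng.shuffle(connections)
            shuffled = ReactorGraphSpec(spec.name, components, connections)
            states = propagate_flows(shuffled, assignment)
            for cid, s in baseline.items():
                assert states[cid].volumetric_flow_ml_min == s.volumetric_flow_ml_min
                assert states[cid].molar_flows == s.molar_flows

    def test_incomplete_assignment_rejected(self):
        with pytest.raises(FlowError, match="INCOMPLETE_ASSIGNMENT"):
            propagate_flows(two_reactor_spec(), {"monomer": InputFeed(0.5)})


class TestResidenceTime:
    def test_volume_over_flow(self):
        spec = two_reactor_spec()
        states = propagate_flows(
            spec,
            {
                "monomer": InputFeed(0.5),
                "catalyst": InputFeed(0.25),
                "quench": InputFeed(0.75),
            },
        )
        assert residence_time(spec, states, "reactor_a") == pytest.approx(0.3 / 0.75)
        assert residence_time(spec, states, "reactor_b") == pytest.approx(0.5 / 1.5)

    def test_unit_quotient(self):
        spec = chain_spec()
        states = propagate_flows(spec, {"feed": InputFeed(2.0)})
        assert residence_time(spec, states, "coil") == pytest.approx(1.0)

    def test_zero_flow_is_an_error(self):
        spec = chain_spec()
        states = propagate_flows(spec, {"feed": InputFeed(0.0)})
        with pytest.raises(FlowError, match="ZERO_FLOW"):
            residence_time(spec, states, "coil")


class TestFlowStoichiometry:
    def test_molar_flow_ratio_oracle(self):
        spec = chain_spec()
        states = propagate_flows(
            spec, {"feed": InputFeed(1.0, (("monomer", 1.0), ("initiator", 0.02)))}
        )
        table = flow_stoichiometry(states, "vial", "initiator")
        assert table.equivalents("monomer") == pytest.approx(50.0)
        assert table.equivalents("initiator") == 1.0

    def test_reference_alone(self):
        spec = chain_spec()
        states = propagate_flows(spec, {"feed": InputFeed(1.0, (("initiator", 0.02),))})
        table = flow_stoichiometry(states, "vial", "initiator")
        assert [r.equivalents for r in table.rows] == [1.0]

    def test_zero_molar_flow_gives_zero_equivalents(self):
        spec = chain_spec()
        states = propagate_flows(
            spec, {"feed": InputFeed(1.0, (("initiator", 0.02), ("monomer", 0.0)))}
        )
        table = flow_stoichiometry(states, "vial", "initiator")
        assert table.equivalents("monomer") == 0.0

    def test_missing_reference_is_an_error(self):
        spec = chain_spec()
        states = propagate_flows(spec, {"feed": InputFeed(1.0)})
        with pytest.raises(StoichiometryError, match="MISSING_REFERENCE"):
            flow_stoichiometry(states, "vial", "initiator")


class TestSankey:
    def test_linear_chain_links_identical(self):
        spec = chain_spec()
        states = propagate_flows(spec, {"feed": InputFeed(0.8)})
        doc = sankey_export(spec, states)
        assert [l["value"] for l in doc["links"]] == [pytest.approx(0.8)] * 2

    def test_link_values_into_node_sum_to_its_flow(self):
        spec, assignment = make_random_reactor(3)
        states = propagate_flows(spec, assignment)
        doc = sankey_export(spec, states)
        incoming: dict[str, float] = {}
        for link in doc["links"]:
            incoming[link["target"]] = incoming.get(link["target"], 0.0) + link["value"]
        for c in spec.components:
            if c.kind != "input":
                assert incoming.get(c.id, 0.0) == pytest.approx(
                    states[c.id].volumetric_flow_ml_min
                )

    def test_all_zero_flows_give_zero_links(self):
        spec = two_reactor_spec()
        states = propagate_flows(
            spec,
            {"monomer": InputFeed(0.0), "catalyst": InputFeed(0.0), "quench": InputFeed(0.0)},
        )
        doc = sankey_export(spec, states)
        assert all(l["value"] == 0.0 for l in doc["links"])


class TestFlowRecordEndToEnd:
    def test_varying_one_input_changes_only_downstream(self):
        """Each flow_reaction is one set of input conditions; re-propagating a
        different quench rate must not disturb anything upstream of its mixer."""
        base = make_record(FixtureSpec(kind="flow_rop"))
        varied = make_record(FixtureSpec(kind="flow_rop", parameters={"quench_rate": 1.5}))
        r1, _ = compile_text(base)
        r2, _ = compile_text(varied)
        s1 = next(r.states for r in r1.reactions if isinstance(r, FlowReaction))
        s2 = next(r.states for r in r2.reactions if isinstance(r, FlowReaction))
        upstream = ["monomer_syringe", "catalyst_syringe", "mixer_a", "reactor_a"]
        for cid in upstream:
            assert s1[cid].volumetric_flow_ml_min == s2[cid].volumetric_flow_ml_min
            assert s1[cid].molar_flows == s2[cid].molar_flows
        assert (
            s2["mixer_b"].volumetric_flow_ml_min > s1["mixer_b"].volumetric_flow_ml_min
        )
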