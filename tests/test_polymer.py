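"""Polymer graphs: construction, composite-tree edge weights, serialization.

The weight computation is checked against an independent brute-force oracle
that writes out every repeat unit of an explicit (small) chain and counts the
bonds of each type directly.
"""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmdl.fixtures import FRAGMENTS, FixtureSpec, make_record
from cmdl.interpreter import compile_text
from cmdl.polymer import (
    PolymerContainer,
    PolymerEdge,
    PolymerGraph,
    PolymerGraphError,
    build_graph,
    canonical_fragment,
    canonical_graph_string,
    compute_edge_weights,
    graphs_equal,
    parse_graph_string,
    PolymerNode,
    serialize_graph_string,
    to_composite_tree,
    validate_fragment,
    weight_graph,
)

END = FRAGMENTS["pyrenebutanol_end"]
REPEAT = FRAGMENTS["valerolactone_repeat"]
CORE2 = FRAGMENTS["butanediol_core"]


def pvl_graph(dp=None) -> PolymerGraph:
    """The two-node poly(valerolactone) graph: end group + repeat unit."""
    root = PolymerContainer(
        id="pvl",
        children=[
            PolymerNode(id="end_group", fragment=END),
            PolymerNode(id="repeat", fragment=REPEAT, dp=dp),
        ],
        edges=[
            PolymerEdge("end_group", "R", "repeat", "Q"),
            PolymerEdge("repeat", "R", "repeat", "Q"),
        ],
    )
    return build_graph("pvl", root)


# ---------------------------------------------------------------------------
# brute-force oracle: enumerate explicit chains and count bond types
# ---------------------------------------------------------------------------


def enumerate_chain_bonds(arms: list[list[str]]) -> dict[tuple[str, str], int]:
    """Bond-type counts of a polymer written out unit by unit.

    ``arms`` lists explicit unit sequences, each starting from the shared
    first unit (an end group or branching core); adjacent units bond.
    Returns counts keyed by (source id, target id) pairs.
    """
    counts: dict[tuple[str, str], int] = {}
    for arm in arms:
        for a, b in zip(arm, arm[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def oracle_weights(arms: list[list[str]]) -> dict[tuple[str, str], Fraction]:
    counts = enumerate_chain_bonds(arms)
    total = sum(counts.values())
    return {k: Fraction(v, total) for k, v in counts.items()}


class TestBuildGraph:
    def test_two_node_homopolymer_structure(self):
        graph = pvl_graph(dp=50)
        assert len(graph.node_paths()) == 2
        assert len(list(graph.iter_edges())) == 2

    def test_single_node_no_edges_is_valid(self):
        g = build_graph(
            "mono", PolymerContainer(id="mono", children=[PolymerNode("only", END)])
        )
        assert g.node_paths() == ["only"]

    def test_edge_naming_undeclared_letter_fails(self):
        root = PolymerContainer(
            id="bad",
            children=[
                PolymerNode(id="end_group", fragment=END),  # declares only R
                PolymerNode(id="repeat", fragment=REPEAT),
            ],
            edges=[PolymerEdge("end_group", "Z", "repeat", "Q")],
        )
        with pytest.raises(PolymerGraphError, match="attachment point"):
            build_graph("bad", root)

    def test_dangling_endpoint_fails(self):
        root = PolymerContainer(
            id="bad",
            children=[PolymerNode(id="end_group", fragment=END)],
            edges=[PolymerEdge("end_group", "R", "ghost", "Q")],
        )
        with pytest.raises(PolymerGraphError, match="not a declared node"):
            build_graph("bad", root)

    def test_disconnected_graph_fails(self):
        root = PolymerContainer(
            id="bad",
            children=[PolymerNode("a", END), PolymerNode("b", END)],
        )
        with pytest.raises(PolymerGraphError, match="not connected"):
            build_graph("bad", root)


class TestCompositeTree:
    def test_explicit_assignments_equal_declared_dp(self):
        declared = weight_graph(pvl_graph(dp=50))
        assigned = weight_graph(pvl_graph(), {"repeat": 50})
        assert graphs_equal(declared, assigned)

    def test_negative_dp_rejected(self):
        with pytest.raises(PolymerGraphError, match=">= 0"):
            to_composite_tree(pvl_graph(), {"repeat": -1})

    def test_tree_total_count_equals_bond_count(self):
        tree = to_composite_tree(pvl_graph(dp=50))
        compute_edge_weights(tree)
        assert tree.total_count() == pytest.approx(50)  # 1 junction + 49 internal


class TestEdgeWeights:
    def test_homopolymer_dp50_worked_example(self):
        """End-to-repeat 1/50, repeat self-edge 49/50."""
        g = weight_graph(pvl_graph(dp=50))
        w = {e.key(): e.weight for e in g.iter_edges()}
        assert w[("end_group", "R", "repeat", "Q")] == pytest.approx(0.02)
        assert w[("repeat", "R", "repeat", "Q")] == pytest.approx(0.98)

    def test_single_unit_chain_has_no_self_bond(self):
        g = weight_graph(pvl_graph(dp=1))
        w = {e.key(): e.weight for e in g.iter_edges()}
        assert w[("end_group", "R", "repeat", "Q")] == 1.0
        assert w[("repeat", "R", "repeat", "Q")] == 0.0

    def test_failed_polymerization_zero_weights_with_warning(self):
        with pytest.warns(UserWarning, match="zero bonds"):
            g = weight_graph(pvl_graph(dp=0))
        assert all(e.weight == 0.0 for e in g.iter_edges())

    @pytest.mark.parametrize("dp", range(1, 13))
    def test_homopolymer_matches_enumerated_chain(self, dp):
        g = weight_graph(pvl_graph(dp=dp))
        expected = oracle_weights([["end"] + ["rep"] * dp])
        w = {e.key(): e.weight for e in g.iter_edges()}
        assert w[("end_group", "R", "repeat", "Q")] == float(expected[("end", "rep")])
        assert w[("repeat", "R", "repeat", "Q")] == float(expected.get(("rep", "rep"), 0))

    @pytest.mark.parametrize("dp_a,dp_b", [(1, 1), (3, 5), (8, 12), (12, 2)])
    def test_block_copolymer_matches_enumerated_chain(self, dp_a, dp_b):
        text = make_record(
            FixtureSpec(kind="block_copolymer", parameters={"dp_a": dp_a, "dp_b": dp_b})
        )
        record, _ = compile_text(text)
        g = record.polymers["block"]
        arms = [["end"] + ["a"] * dp_a + ["b"] * dp_b]
        expected = oracle_weights(arms)
        w = {e.key(): e.weight for e in g.iter_edges()}
        assert w[("end_group", "R", "block_a", "Q")] == float(expected[("end", "a")])
        assert w[("block_a", "R", "block_a", "Q")] == float(expected.get(("a", "a"), 0))
        assert w[("block_a", "R", "block_b", "Q")] == float(expected[("a", "b")])
        assert w[("block_b", "R", "block_b", "Q")] == float(expected.get(("b", "b"), 0))

    @pytest.mark.parametrize("q,kind", [(2, "diol_telechelic"), (3, "dendrimer"), (4, "dendrimer")])
    @pytest.mark.parametrize("dp", [1, 4, 12])
    def test_star_architectures_match_enumerated_arms(self, q, kind, dp):
        params = {"dp": dp} if kind == "diol_telechelic" else {"dp": dp, "q": q}
        record, _ = compile_text(make_record(FixtureSpec(kind=kind, parameters=params)))
        g = list(record.polymers.values())[0]
        arms = [["core"] + ["arm"] * dp for _ in range(q)]
        expected = oracle_weights(arms)
        w = {e.key(): e.weight for e in g.iter_edges()}
        assert w[("core", "R", "arm", "Q")] == float(expected[("core", "arm")])
        assert w[("arm", "R", "arm", "Q")] == float(expected.get(("arm", "arm"), 0))

    @pytest.mark.parametrize("q,kind", [(2, "diol_telechelic"), (3, "dendrimer"), (4, "dendrimer")])
    def test_quantity_compression_equals_expanded_graph(self, q, kind):
        """An edge-quantity q graph weighs exactly like q explicit branches."""
        params = {"dp": 50} if kind == "diol_telechelic" else {"dp": 50, "q": q}
        compressed, _ = compile_text(make_record(FixtureSpec(kind=kind, parameters=params)))
        expanded, _ = compile_text(
            make_record(FixtureSpec(kind=kind, parameters={**params, "expanded": True}))
        )
        wc = {e.key(): e.weight for e in list(compressed.polymers.values())[0].iter_edges()}
        we = {e.key(): e.weight for e in list(expanded.polymers.values())[0].iter_edges()}
        junction = sum(w for (s, _, t, _), w in we.items() if s == "core")
        self_bonds = sum(w for (s, _, t, _), w in we.items() if s != "core")
        assert wc[("core", "R", "arm", "Q")] == pytest.approx(junction, abs=1e-15)
        assert wc[("arm", "R", "arm", "Q")] == pytest.approx(self_bonds, abs=1e-15)

    def test_statistical_container_random_enchainment_fractions(self):
        text = make_record(
            FixtureSpec(kind="statistical_copolymer", parameters={"dp_a": 30, "dp_b": 20})
        )
        record, _ = compile_text(text)
        g = record.polymers["statistical"]
        w = {e.key(): e.weight for e in g.iter_edges()}
        n, fa, fb = 50, 0.6, 0.4
        total = 1 + (n - 1)  # junction + internal bonds
        assert w[("stat.unit_a", "R", "stat.unit_a", "Q")] == pytest.approx((n - 1) * fa**2 / total)
        assert w[("stat.unit_a", "R", "stat.unit_b", "Q")] == pytest.approx(
            (n - 1) * 2 * fa * fb / total
        )
        assert w[("stat.unit_b", "R", "stat.unit_b", "Q")] == pytest.approx((n - 1) * fb**2 / total)
        assert w[("end_group", "R", "stat.unit_a", "Q")] == pytest.approx(1 / total)

    def test_statistical_pure_composition_reduces_to_block_counts(self):
        """As the composition goes pure, statistical counts approach a block's."""
        text = make_record(
            FixtureSpec(kind="statistical_copolymer", parameters={"dp_a": 50, "dp_b": 0})
        )
        record, _ = compile_text(text)
        w = {e.key(): e.weight for e in record.polymers["statistical"].iter_edges()}
        assert w[("stat.unit_a", "R", "stat.unit_a", "Q")] == pytest.approx(49 / 50)
        assert w[("stat.unit_a", "R", "stat.unit_b", "Q")] == 0.0
        assert w[("stat.unit_b", "R", "stat.unit_b", "Q")] == 0.0

    @settings(max_examples=60, deadline=None)
    @given(
        dp_a=st.integers(min_value=0, max_value=200),
        dp_b=st.integers(min_value=0, max_value=200),
        q=st.integers(min_value=1, max_value=4),
    )
    def test_weights_always_sum_to_one(self, dp_a, dp_b, q):
        """Normalization invariant over random DP_n and quantities."""
        root = PolymerContainer(
            id="g",
            children=[
                PolymerNode("core", CORE2),
                PolymerNode("a", REPEAT, dp=dp_a),
                PolymerNode("b", FRAGMENTS["tmc_repeat"], dp=dp_b),
            ],
            edges=[
                PolymerEdge("core", "R", "a", "Q", quantity=q),
                PolymerEdge("a", "R", "a", "Q", quantity=q),
                PolymerEdge("a", "R", "b", "Q"),
                PolymerEdge("b", "R", "b", "Q"),
            ],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = compute_edge_weights(to_composite_tree(build_graph("g", root)))
        total = sum(e.weight for e in g.iter_edges())
        assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0


class TestSerialization:
    def test_trivial_single_node_string(self):
        g = build_graph(
            "mono", PolymerContainer(id="mono", children=[PolymerNode("only", END)])
        )
        s = serialize_graph_string(g)
        assert s.count("(") == s.count(")") >= 1
        assert "<" not in s.replace("<graph:mono>", "")

    def test_two_node_graph_has_two_edge_terms(self):
        s = serialize_graph_string(weight_graph(pvl_graph(dp=50)))
        edge_terms = [t for t in s.split() if t.startswith("<") and "|" in t]
        assert len(edge_terms) == 2
        assert "<end_group.R|repeat.Q|0.0200>" in s
        assert "<repeat.R|repeat.Q|0.9800>" in s

    def test_round_trip_on_fixture_corpus(self, corpus_graphs):
        for g in corpus_graphs:
            out = parse_graph_string(serialize_graph_string(g))
            assert out.ok, out.failure
            assert graphs_equal(g, out.graph)

    def test_serialization_is_bijective_on_corpus(self, corpus_graphs):
        strings = {serialize_graph_string(g) for g in corpus_graphs}
        assert len(strings) == len(corpus_graphs)
        for s in strings:
            assert serialize_graph_string(parse_graph_string(s).graph) == s

    def test_properties_survive_round_trip(self):
        s = serialize_graph_string(weight_graph(pvl_graph(dp=50)), {"PDI": 1.16})
        out = parse_graph_string(s)
        assert out.properties == {"PDI": "1.16"}

    def test_truncated_fragment_reports_unbalanced(self):
        out = parse_graph_string("a([R]C(=O)CC")
        assert not out.ok
        assert out.failure.kind == "UNBALANCED_SMILES"

    def test_empty_string_reports_empty(self):
        out = parse_graph_string("")
        assert not out.ok and out.failure.kind == "EMPTY"

    def test_dangling_edge_reports_failure(self):
        out = parse_graph_string("a([R]CO) <a.R|ghost.Q>")
        assert not out.ok and out.failure.kind == "DANGLING_EDGE"


class TestFragments:
    def test_valerolactone_repeat_is_valid(self):
        ok, reason = validate_fragment("[R]C(=O)CCCCO[Q]")
        assert ok and reason == "OK"

    def test_pentavalent_carbon_is_valence_invalid(self):
        ok, reason = validate_fragment("C(C)(C)(C)(C)C")
        assert not ok and reason == "VALENCE"

    def test_unclosed_ring_reports_ring(self):
        ok, reason = validate_fragment("[R]C1CCCC")
        assert not ok and reason == "RING"

    def test_unbalanced_parenthesis_reports_paren(self):
        ok, reason = validate_fragment("[R]C(=O)CC(")
        assert not ok and reason == "PAREN"

    def test_canonical_fragment_merges_equivalent_writings(self):
        a = canonical_fragment("[R]C(=O)CCCCO[Q]")
        b = canonical_fragment("[Q]OCCCCC(=O)[R]")
        assert a == b

    def test_canonical_graph_string_strips_weights(self, corpus_graphs):
        for g in corpus_graphs:
            s = canonical_graph_string(g)
            assert "|0." not in s and "|1." not in s
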