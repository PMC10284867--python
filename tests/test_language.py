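"""Lexer, parser, validator and interpreter behaviour of the record language."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmdl import fixtures as fx
from cmdl.diagnostics import Severity, has_errors
from cmdl.export import export_json
from cmdl.interpreter import compile_text, interpret
from cmdl.lexer import Token, TokenKind, reconstruct, tokenize
from cmdl.parser import Reference, parse, parse_text, serialize_ast
from cmdl.units import Quantity
from cmdl.validator import validate

CHEMICAL = """
chemical mba {
    smiles: "Cc1ccc(CO)cc1";
    molar_mass: 122.17 g/mol;  # 4-methylbenzyl alcohol
    role: initiator;
}
"""


class TestTokenize:
    def test_empty_text_yields_only_eof(self):
        tokens = tokenize("")
        assert [t.kind for t in tokens] == [TokenKind.EOF]

    def test_mass_quantity_lexes_as_number_plus_unit(self):
        # bench notation: "4-MBA (4.9 mg, 0.04 mmol, 1 eq)"
        tokens = tokenize("mass: 4.9 mg;")
        kinds = [(t.kind, t.lexeme) for t in tokens if t.kind is not TokenKind.EOF]
        assert (TokenKind.NUMBER, "4.9") in kinds
        assert (TokenKind.UNIT, "mg") in kinds

    def test_illegal_character_becomes_error_token(self):
        tokens = tokenize("chemical a \x01 {}")
        errors = [t for t in tokens if t.kind is TokenKind.ERROR]
        assert len(errors) == 1
        assert errors[0].lexeme == "\x01"
        assert errors[0].column == 12

    def test_positions_monotone_and_lexemes_nonempty(self, corpus):
        for text, _ in corpus.values():
            tokens = tokenize(text)
            for a, b in zip(tokens, tokens[1:]):
                assert (a.line, a.column) <= (b.line, b.column)
            assert all(t.lexeme for t in tokens if t.kind is not TokenKind.EOF)

    def test_reconstruction_of_fixture_corpus(self, corpus):
        for text, _ in corpus.values():
            assert reconstruct(tokenize(text)) == text

    @settings(max_examples=200, deadline=None)
    @given(st.text(max_size=300))
    def test_reconstruction_on_arbitrary_text(self, text):
        """Trivia plus lexemes always reproduce the input, crash-free."""
        assert reconstruct(tokenize(text)) == text


class TestParse:
    def test_single_chemical_group(self):
        groups, diags = parse_text(CHEMICAL)
        assert not diags
        assert len(groups) == 1
        assert groups[0].group_type == "chemical"
        assert groups[0].name == "mba"
        mm = groups[0].get("molar_mass")
        assert isinstance(mm, Quantity) and mm.value == pytest.approx(122.17)

    def test_declare_then_reference(self):
        """A polymer graph defined separately is referenced by a result group."""
        text = fx.make_record(fx.FixtureSpec(kind="homopolymer")) + (
            "\nresult r1 {\n    polymer: @pvl;\n    dispersity: 1.1;\n}\n"
        )
        groups, diags = parse_text(text)
        assert not diags
        assert [g.group_type for g in groups] == ["polymer_graph", "result"]
        ref = groups[1].get("polymer")
        assert isinstance(ref, Reference) and ref.root == "pvl"

    def test_unclosed_group_recovers(self):
        text = 'chemical a {\n    role: monomer;\n\nchemical b {\n    role: solvent;\n}\n'
        groups, diags = parse_text(text)
        assert [g.name for g in groups] == ["a", "b"]
        assert any(d.code == "UNCLOSED_GROUP" for d in diags)

    def test_corrupted_group_does_not_hide_neighbours(self, corpus):
        """One corrupted group in an N-group document still yields N+1 items."""
        text, _ = corpus["batch_rop"]
        n_groups = len(parse_text(text)[0])
        corrupted = text + "\nreaction broken { mass 4.9 ;;; }\n"
        groups, diags = parse_text(corrupted)
        assert len(groups) + (1 if diags else 0) >= n_groups + 1
        assert len(groups) >= n_groups

    def test_ast_round_trip(self, corpus):
        """serialize(parse(text)) reparses to an equal AST."""
        for text, _ in corpus.values():
            groups, diags = parse_text(text)
            assert not diags
            rendered = serialize_ast(groups)
            reparsed, diags2 = parse_text(rendered)
            assert not diags2
            assert reparsed == groups
            assert serialize_ast(reparsed) == rendered


class TestValidate:
    def test_clean_fixtures_have_no_errors(self, corpus):
        for kind, (text, _) in corpus.items():
            groups, parse_diags = parse_text(text)
            diags = parse_diags + validate(groups)
            assert not has_errors(diags), f"{kind}: {diags}"

    def test_missing_molar_mass_in_reaction(self):
        text = (
            "chemical x {\n    role: monomer;\n}\n"
            "chemical init {\n    molar_mass: 100 g/mol;\n    role: initiator;\n}\n"
            "reaction r {\n"
            "    reagent { entity: @init; mass: 10 mg; }\n"
            "    reagent { entity: @x; mass: 5 mg; }\n"
            "}\n"
        )
        groups, _ = parse_text(text)
        codes = {d.code for d in validate(groups)}
        assert "MISSING_MOLAR_MASS" in codes

    def test_flow_rate_with_mass_unit_is_wrong_dimension(self):
        text = (
            "reactor_graph rig {\n"
            "    component a { kind: input; }\n"
            "    component z { kind: collection; }\n"
            "    connect { from: @a; to: @z; }\n"
            "}\n"
            "flow_reaction run {\n"
            "    reactor: @rig;\n"
            "    input { component: @rig.a; flow_rate: 5 mg; }\n"
            "}\n"
        )
        groups, _ = parse_text(text)
        codes = {d.code for d in validate(groups)}
        assert "WRONG_DIMENSION" in codes

    def test_unresolved_reference(self):
        text = "result r {\n    polymer: @ghost;\n}\n"
        groups, _ = parse_text(text)
        codes = {d.code for d in validate(groups)}
        assert "UNRESOLVED_REFERENCE" in codes

    def test_duplicate_declaration_is_an_error(self):
        text = CHEMICAL + CHEMICAL
        groups, _ = parse_text(text)
        codes = {d.code for d in validate(groups)}
        assert "DUPLICATE_NAME" in codes

    def test_unknown_property_is_a_warning_not_error(self):
        text = 'chemical a {\n    colour: "blue";\n}\n'
        groups, _ = parse_text(text)
        diags = validate(groups)
        assert any(d.code == "UNKNOWN_PROPERTY" for d in diags)
        assert not has_errors(diags)


class TestInterpret:
    def test_interpretation_is_deterministic(self, corpus):
        for kind, (text, record) in corpus.items():
            again, diags = compile_text(text)
            assert not has_errors(diags)
            assert export_json(again) == export_json(record), kind

    def test_batch_reaction_materializes_table(self, corpus):
        _, record = corpus["batch_rop"]
        from cmdl.records import BatchReaction

        tables = [r.table for r in record.reactions if isinstance(r, BatchReaction)]
        assert len(tables) == 1
        assert len(tables[0].rows) == 4  # initiator, catalyst, monomer, solvent

    def test_homopolymer_record_carries_two_weighted_edges(self, corpus):
        _, record = corpus["homopolymer"]
        graph = record.polymers["pvl"]
        edges = list(graph.iter_edges())
        assert len(edges) == 2
        assert all(e.weight is not None for e in edges)

    def test_flow_record_propagates_to_collection(self, corpus):
        _, record = corpus["flow_rop"]
        from cmdl.records import FlowReaction

        run = next(r for r in record.reactions if isinstance(r, FlowReaction))
        collected = run.states["collection"]
        assert collected.volumetric_flow_ml_min == pytest.approx(1.5)
        assert set(collected.molar_flows) == {
            "valerolactone",
            "dbu",
            "pyrenebutanol",
            "benzoic_acid",
        }

    def test_interpret_refuses_error_diagnostics(self):
        groups, _ = parse_text("result r {\n    polymer: @ghost;\n}\n")
        from cmdl.interpreter import CompilationError

        with pytest.raises(CompilationError):
            interpret(groups)
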