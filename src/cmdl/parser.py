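"""Recursive-descent parser building CMDL abstract syntax trees.

Grammar (EBNF-ish)::

    document  := group*
    group     := KEYWORD [IDENTIFIER] block
    block     := '{' (property | group)* '}'
    property  := key ':' value ';'
    key       := IDENTIFIER | KEYWORD
    value     := NUMBER [UNIT] | STRING | REFERENCE | IDENTIFIER | list
    list      := '[' [value (',' value)*] ']'

The parser never raises on malformed input: it records a diagnostic and
resynchronizes at the next top-level keyword or closing brace, so one
corrupted group does not hide the groups that follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .diagnostics import Diagnostic, error
from .lexer import Token, TokenKind, tokenize
from .units import Quantity, parse_quantity

__all__ = [
    "AstGroup",
    "Reference",
    "AstValue",
    "parse",
    "parse_text",
    "serialize_ast",
]

REFERENCE_SIGIL = "@"

GROUP_TYPES = frozenset(
    {
        "chemical",
        "polymer",
        "polymer_graph",
        "reactor_graph",
        "reaction",
        "flow_reaction",
        "result",
        "fragment",
    }
)

NESTED_KINDS = frozenset(
    {"container", "node", "edge", "reagent", "component", "connect", "input", "solution", "dp"}
)


@dataclass(frozen=True)
class Reference:
    """A ``@name`` or ``@name.path`` value pointing at a declared entity."""

    path: tuple[str, ...]

    @property
    def text(self) -> str:
        return REFERENCE_SIGIL + ".".join(self.path)

    @property
    def root(self) -> str:
        return self.path[0]


AstValue = Union[float, str, bool, Quantity, Reference, list, "AstGroup"]


@dataclass
class AstGroup:
    """One block group: ``groupType name { key: value; ... }``.

    Nested groups appear in ``properties`` keyed by their block keyword
    (``node``, ``edge``, ...), possibly repeated.
    """

    group_type: str
    name: str
    properties: list[tuple[str, AstValue]] = field(default_factory=list)
    line: int = field(default=0, compare=False)
    column: int = field(default=0, compare=False)
    anonymous: bool = field(default=False, compare=False)

    def get(self, key: str, default: AstValue | None = None) -> AstValue | None:
        for k, v in self.properties:
            if k == key:
                return v
        return default

    def get_all(self, key: str) -> list[AstValue]:
        return [v for k, v in self.properties if k == key]

    def children(self) -> list["AstGroup"]:
        return [v for _, v in self.properties if isinstance(v, AstGroup)]


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = [t for t in tokens if t.kind is not TokenKind.EOF]
        self.pos = 0
        self.diags: list[Diagnostic] = []
        self._anon_counter = 0

    # -- token helpers -------------------------------------------------
    def peek(self) -> Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> Token | None:
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def expect_punct(self, ch: str) -> Token | None:
        tok = self.peek()
        if tok and tok.kind is TokenKind.PUNCT and tok.lexeme == ch:
            return self.next()
        return None

    def err(self, code: str, message: str, tok: Token | None) -> None:
        line = tok.line if tok else 0
        col = tok.column if tok else 0
        self.diags.append(error(code, message, line, col))

    # -- grammar -------------------------------------------------------
    def parse_document(self) -> list[AstGroup]:
        groups: list[AstGroup] = []
        while (tok := self.peek()) is not None:
            if tok.kind is TokenKind.KEYWORD and tok.lexeme in GROUP_TYPES:
                group = self.parse_group(top_level=True)
                if group is not None:
                    groups.append(group)
            else:
                self.err(
                    "UNEXPECTED_TOKEN",
                    f"expected a group keyword, found {tok.lexeme!r}",
                    tok,
                )
                self.synchronize_top()
        return groups

    def synchronize_top(self) -> None:
        """Skip ahead to the next plausible top-level group start."""
        depth = 0
        while (tok := self.peek()) is not None:
            if tok.kind is TokenKind.PUNCT and tok.lexeme == "{":
                depth += 1
            elif tok.kind is TokenKind.PUNCT and tok.lexeme == "}":
                if depth == 0:
                    self.next()
                    return
                depth -= 1
            elif depth == 0 and tok.kind is TokenKind.KEYWORD and tok.lexeme in GROUP_TYPES:
                return
            self.next()

    def parse_group(self, top_level: bool) -> AstGroup | None:
        kw = self.next()
        assert kw is not None
        name_tok = self.peek()
        anonymous = False
        if name_tok and name_tok.kind in (TokenKind.IDENTIFIER, TokenKind.KEYWORD) and not (
            name_tok.kind is TokenKind.KEYWORD and name_tok.lexeme in GROUP_TYPES | NESTED_KINDS
        ):
            name = name_tok.lexeme
            self.next()
        elif name_tok and name_tok.kind is TokenKind.PUNCT and name_tok.lexeme == "{":
            self._anon_counter += 1
            name = f"{kw.lexeme}_{self._anon_counter}"
            anonymous = True
        else:
            self.err("MISSING_NAME", f"group {kw.lexeme!r} lacks a name", kw)
            self.synchronize_top()
            return None

        group = AstGroup(kw.lexeme, name, line=kw.line, column=kw.column, anonymous=anonymous)
        if not self.expect_punct("{"):
            self.err("MISSING_BLOCK", f"group {name!r} lacks an opening '{{'", self.peek() or kw)
            self.synchronize_top()
            return None
        self.parse_block(group)
        return group

    def parse_block(self, group: AstGroup) -> None:
        while True:
            tok = self.peek()
            if tok is None:
                self.err("UNCLOSED_GROUP", f"group {group.name!r} is never closed", tok)
                return
            if tok.kind is TokenKind.PUNCT and tok.lexeme == "}":
                self.next()
                return
            if tok.kind is TokenKind.KEYWORD and tok.lexeme in NESTED_KINDS:
                # nested group or a property whose key collides with a keyword
                after = self.tokens[self.pos + 1] if self.pos + 1 < len(self.tokens) else None
                if after and after.kind is TokenKind.PUNCT and after.lexeme == ":":
                    self.parse_property(group)
                    continue
                nested = self.parse_group(top_level=False)
                if nested is not None:
                    group.properties.append((nested.group_type, nested))
                continue
            if tok.kind is TokenKind.KEYWORD and tok.lexeme in GROUP_TYPES:
                after = self.tokens[self.pos + 1] if self.pos + 1 < len(self.tokens) else None
                if not (after and after.kind is TokenKind.PUNCT and after.lexeme == ":"):
                    # a new top-level group begins: this one was never closed
                    self.err(
                        "UNCLOSED_GROUP", f"group {group.name!r} is never closed", tok
                    )
                    return
            if tok.kind in (TokenKind.IDENTIFIER, TokenKind.KEYWORD):
                self.parse_property(group)
                continue
            self.err("UNEXPECTED_TOKEN", f"unexpected {tok.lexeme!r} in group body", tok)
            self.next()

    def parse_property(self, group: AstGroup) -> None:
        key_tok = self.next()
        assert key_tok is not None
        if not self.expect_punct(":"):
            self.err("MISSING_COLON", f"property {key_tok.lexeme!r} lacks ':'", key_tok)
            self.skip_to_semicolon()
            return
        value = self.parse_value()
        if value is None:
            self.skip_to_semicolon()
            return
        if not self.expect_punct(";"):
            self.err("MISSING_SEMICOLON", f"property {key_tok.lexeme!r} lacks ';'", key_tok)
            self.skip_to_semicolon()
        group.properties.append((key_tok.lexeme, value))

    def skip_to_semicolon(self) -> None:
        while (tok := self.peek()) is not None:
            if tok.kind is TokenKind.PUNCT and tok.lexeme in ";":
                self.next()
                return
            if tok.kind is TokenKind.PUNCT and tok.lexeme == "}":
                return
            self.next()

    def parse_value(self) -> AstValue | None:
        tok = self.peek()
        if tok is None:
            self.err("MISSING_VALUE", "expected a value", tok)
            return None
        if tok.kind is TokenKind.NUMBER:
            self.next()
            number = float(tok.lexeme)
            unit_tok = self.peek()
            if unit_tok and unit_tok.kind is TokenKind.UNIT:
                self.next()
                return parse_quantity(number, unit_tok.lexeme)
            return number
        if tok.kind is TokenKind.STRING:
            self.next()
            return tok.lexeme[1:-1].replace('\\"', '"')
        if tok.kind is TokenKind.REFERENCE:
            self.next()
            return Reference(tuple(tok.lexeme[1:].split(".")))
        if tok.kind is TokenKind.IDENTIFIER or tok.kind is TokenKind.KEYWORD:
            self.next()
            if tok.lexeme == "true":
                return True
            if tok.lexeme == "false":
                return False
            return tok.lexeme
        if tok.kind is TokenKind.PUNCT and tok.lexeme == "[":
            self.next()
            items: list[AstValue] = []
            if self.expect_punct("]"):
                return items
            while True:
                item = self.parse_value()
                if item is None:
                    return items
                items.append(item)
                if self.expect_punct("]"):
                    return items
                if not self.expect_punct(","):
                    self.err("MISSING_COMMA", "expected ',' or ']' in list", self.peek())
                    return items
        self.err("BAD_VALUE", f"cannot parse value starting at {tok.lexeme!r}", tok)
        self.next()
        return None


def parse(tokens: list[Token]) -> tuple[list[AstGroup], list[Diagnostic]]:
    """Parse a token stream into top-level AST groups plus diagnostics."""
    parser = _Parser(tokens)
    groups = parser.parse_document()
    return groups, parser.diags


def parse_text(text: str) -> tuple[list[AstGroup], list[Diagnostic]]:
    return parse(tokenize(text))


# ---------------------------------------------------------------------------
# canonical formatting (serialize AST back to CMDL text)
# ---------------------------------------------------------------------------


def _format_value(value: AstValue) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value) if value != int(value) else str(int(value))
    if isinstance(value, Quantity):
        num = repr(value.value) if value.value != int(value.value) else str(int(value.value))
        return f"{num} {value.unit}" if value.unit else f"{num} eq"
    if isinstance(value, Reference):
        return value.text
    if isinstance(value, str):
        return f'"{value}"' if not value.isidentifier() else value
    if isinstance(value, list):
        return "[" + ", ".join(_format_value(v) for v in value) + "]"
    raise TypeError(f"unexpected value {value!r}")


def _format_group(group: AstGroup, indent: int) -> str:
    pad = "    " * indent
    head = f"{pad}{group.group_type} {group.name} {{" if not group.anonymous else f"{pad}{group.group_type} {{"
    lines = [head]
    for key, value in group.properties:
        if isinstance(value, AstGroup):
            lines.append(_format_group(value, indent + 1))
        else:
            lines.append(f"{pad}    {key}: {_format_value(value)};")
    lines.append(pad + "}")
    return "\n".join(lines)


def serialize_ast(groups: list[AstGroup]) -> str:
    """Render groups as canonical CMDL text; reparsing yields an equal AST."""
    return "\n\n".join(_format_group(g, 0) for g in groups) + "\n"
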