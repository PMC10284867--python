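"""Tokenizer for CMDL record text.

The surface syntax is line-oriented blocks::

    chemical DBU {
        smiles: "C1CCC2=NCCCN2CC1";
        molar_mass: 152.24 g/mol;
        role: catalyst;
    }

Tokens carry their source position and the whitespace/comment trivia that
preceded them, so the token stream reconstructs the input text exactly —
a prerequisite for lossless formatting and precise diagnostics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .units import known_unit

__all__ = ["TokenKind", "Token", "tokenize", "reconstruct", "KEYWORDS"]


class TokenKind(str, Enum):
    KEYWORD = "keyword"
    IDENTIFIER = "identifier"
    REFERENCE = "reference"
    NUMBER = "number"
    UNIT = "unit"
    STRING = "string"
    PUNCT = "punct"
    ERROR = "error"
    EOF = "eof"


# Group-level and nested-block keywords of the language.
KEYWORDS = frozenset(
    {
        # top-level group types
        "chemical",
        "polymer",
        "polymer_graph",
        "reactor_graph",
        "reaction",
        "flow_reaction",
        "result",
        "fragment",
        # nested block kinds
        "container",
        "node",
        "edge",
        "reagent",
        "component",
        "connect",
        "input",
        "solution",
        "dp",
    }
)

_PUNCT = frozenset("{}:;,[]")

_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_\-]*")
_REFERENCE_RE = re.compile(r"@[A-Za-z_][A-Za-z0-9_\-]*(?:\.[A-Za-z_][A-Za-z0-9_\-]*)*")
# possible unit lexeme directly after a number, e.g. "mg", "mL/min", "%", "µL"
_UNIT_RE = re.compile(r"%|[A-Za-zµ][A-Za-z]*(?:/[A-Za-z]+)?")


@dataclass(frozen=True)
class Token:
    kind: TokenKind
    lexeme: str
    line: int
    column: int
    trivia: str = field(default="", compare=False)


def tokenize(text: str) -> list[Token]:
    """Tokenize CMDL text; unknown characters become error tokens, never raise.

    The concatenation of every token's ``trivia + lexeme`` (including the
    final EOF token) reproduces the input exactly.
    """
    tokens: list[Token] = []
    i = 0
    line, col = 1, 1
    n = len(text)
    trivia_start = 0

    def advance(lexeme: str) -> None:
        nonlocal line, col
        newlines = lexeme.count("\n")
        if newlines:
            line += newlines
            col = len(lexeme) - lexeme.rfind("\n")
        else:
            col += len(lexeme)

    def emit(kind: TokenKind, lexeme: str) -> None:
        nonlocal i, trivia_start
        tokens.append(Token(kind, lexeme, line, col, text[trivia_start:i]))
        i += len(lexeme)
        advance(lexeme)
        trivia_start = i

    while i < n:
        ch = text[i]
        # whitespace / comments are trivia
        if ch in " \t\r\n":
            i += 1
            advance(ch)
            continue
        if ch == "#":
            end = text.find("\n", i)
            end = n if end == -1 else end
            skipped = text[i:end]
            i = end
            advance(skipped)
            continue
        if ch in _PUNCT:
            emit(TokenKind.PUNCT, ch)
            continue
        if ch == '"':
            m = re.match(r'"(?:[^"\\\n]|\\.)*"', text[i:])
            if m:
                emit(TokenKind.STRING, m.group(0))
            else:  # unterminated string: consume to end of line
                end = text.find("\n", i)
                end = n if end == -1 else end
                emit(TokenKind.ERROR, text[i:end] or '"')
            continue
        if ch == "@":
            m = _REFERENCE_RE.match(text, i)
            if m:
                emit(TokenKind.REFERENCE, m.group(0))
            else:
                emit(TokenKind.ERROR, ch)
            continue
        m = _NUMBER_RE.match(text, i)
        if m and (ch.isdigit() or (ch in "+-" and i + 1 < n and text[i + 1].isdigit())):
            emit(TokenKind.NUMBER, m.group(0))
            # a unit may follow the number after spaces
            j = i
            while j < n and text[j] in " \t":
                j += 1
            um = _UNIT_RE.match(text, j)
            if um and known_unit(um.group(0)):
                ws = text[i:j]
                if ws:
                    advance(ws)
                    i = j
                emit(TokenKind.UNIT, um.group(0))
            continue
        m = _IDENT_RE.match(text, i)
        if m:
            lexeme = m.group(0)
            kind = TokenKind.KEYWORD if lexeme in KEYWORDS else TokenKind.IDENTIFIER
            emit(kind, lexeme)
            continue
        # unknown character: error token, keep going
        emit(TokenKind.ERROR, ch)

    tokens.append(Token(TokenKind.EOF, "", line, col, text[trivia_start:]))
    return tokens


def reconstruct(tokens: list[Token]) -> str:
    """Inverse of :func:`tokenize` with respect to the raw text."""
    return "".join(t.trivia + t.lexeme for t in tokens)
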