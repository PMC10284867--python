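"""Diagnostics shared by the compiler stages (lexing, parsing, validation)."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Diagnostic:
    """A compiler finding tied to a source location.

    Errors block interpretation; warnings do not.
    """

    severity: Severity
    code: str
    message: str
    line: int = 0
    column: int = 0

    def render(self) -> str:
        return f"{self.severity.value} {self.code} {self.line}:{self.column} {self.message}"


def error(code: str, message: str, line: int = 0, column: int = 0) -> Diagnostic:
    return Diagnostic(Severity.ERROR, code, message, line, column)


def warning(code: str, message: str, line: int = 0, column: int = 0) -> Diagnostic:
    return Diagnostic(Severity.WARNING, code, message, line, column)


def has_errors(diags: list[Diagnostic]) -> bool:
    return any(d.severity is Severity.ERROR for d in diags)
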