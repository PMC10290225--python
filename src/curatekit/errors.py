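"""Exception hierarchy for recipe parsing, compilation and execution."""

from __future__ import annotations


class CuratekitError(Exception):
    """Base class for all errors raised by this package."""


class RecipeError(CuratekitError):
    """A recipe could not be parsed.

    Carries an optional source line and key path so the CLI can point
    authors at the offending spot in the TOML file.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 keypath: str | None = None) -> None:
        self.line = line
        self.keypath = keypath
        parts = [message]
        if keypath:
            parts.append(f"(at {keypath})")
        if line is not None:
            parts.append(f"(line {line})")
        super().__init__(" ".join(parts))


class CompileError(CuratekitError):
    """A parsed recipe failed semantic validation and cannot be compiled."""

    def __init__(self, message: str, diagnostics: list | None = None) -> None:
        self.diagnostics = diagnostics or []
        super().__init__(message)


class ExecutionError(CuratekitError):
    """A runtime failure during traversal (I/O, failing action)."""


class RegistryError(CuratekitError):
    """Illegal registry manipulation, e.g. shadowing a built-in symbol."""
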