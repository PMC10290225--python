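"""Symbol expressions: the names a recipe uses for conditions and actions.

A recipe refers to conditions/actions by name, optionally currying literal
arguments and nesting combinators.  The TOML encoding is:

* a bare string ``"is_file"`` — a zero-argument symbol;
* the prefix token ``"not "`` negates: ``"not is_file"``;
* an array whose first element is the (possibly negated) name and whose
  remaining elements are literal arguments (strings, numbers, booleans)
  or nested expressions: ``["has_extension", ".csv"]``,
  ``["all_of", "is_file", ["not has_extension", ".tmp"]]``.

Combinators (``all_of``, ``any_of``, ``not``) take expressions as
arguments and may nest arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .errors import RecipeError

#: names resolved structurally (their arguments are sub-expressions)
COMBINATORS = frozenset({"all_of", "any_of", "not"})

NEGATION_PREFIX = "not "

Literal = Union[str, int, float, bool]


@dataclass(frozen=True)
class SymbolExpr:
    """A reference to a named condition or action with bound arguments."""

    name: str
    args: tuple = ()
    negated: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("symbol name must be non-empty")

    def referenced_names(self) -> set[str]:
        """All symbol names mentioned anywhere in this expression tree."""
        names = {self.name}
        for a in self.args:
            if isinstance(a, SymbolExpr):
                names |= a.referenced_names()
        return names


def parse_symbol(value, keypath: str = "") -> SymbolExpr:
    """Build a :class:`SymbolExpr` from its TOML encoding."""
    if isinstance(value, str):
        name, negated = _split_negation(value, keypath)
        return SymbolExpr(name=name, negated=negated)
    if isinstance(value, list):
        if not value or not isinstance(value[0], str):
            raise RecipeError(
                "symbol array must start with a name string", keypath=keypath)
        name, negated = _split_negation(value[0], keypath)
        if name in COMBINATORS:
            # combinator arguments are themselves expressions
            args = tuple(parse_symbol(v, keypath) for v in value[1:])
        else:
            args = tuple(_parse_arg(v, keypath) for v in value[1:])
        return SymbolExpr(name=name, args=args, negated=negated)
    raise RecipeError(
        f"expected a symbol (string or array), got {type(value).__name__}",
        keypath=keypath)


def _split_negation(token: str, keypath: str) -> tuple[str, bool]:
    token = token.strip()
    negated = False
    if token.startswith(NEGATION_PREFIX):
        negated = True
        token = token[len(NEGATION_PREFIX):].strip()
    if not token:
        raise RecipeError("empty symbol name", keypath=keypath)
    return token, negated


def _parse_arg(value, keypath: str):
    # bool is a subclass of int; keep it a literal, not a symbol
    if isinstance(value, (bool, int, float)):
        return value
    if isinstance(value, str):
        return value
    if isinstance(value, list):
        return parse_symbol(value, keypath)
    raise RecipeError(
        f"unsupported literal of type {type(value).__name__}", keypath=keypath)


def serialize_symbol(expr: SymbolExpr):
    """Inverse of :func:`parse_symbol` (canonical TOML value)."""
    name = (NEGATION_PREFIX + expr.name) if expr.negated else expr.name
    if not expr.args:
        return name
    out = [name]
    for a in expr.args:
        out.append(serialize_symbol(a) if isinstance(a, SymbolExpr) else a)
    return out


def expand_aliases(expr: SymbolExpr, aliases: dict[str, SymbolExpr],
                   _stack: tuple = ()) -> SymbolExpr:
    """Substitute shared-definition aliases, rejecting cycles.

    An alias with arguments cannot itself be re-curried; referencing an
    alias with extra arguments is an error caught at validation time.
    """
    if expr.name in _stack:
        chain = " -> ".join(_stack + (expr.name,))
        raise RecipeError(f"alias cycle: {chain}")
    args = tuple(
        expand_aliases(a, aliases, _stack) if isinstance(a, SymbolExpr) else a
        for a in expr.args)
    if expr.name in aliases:
        target = expand_aliases(aliases[expr.name], aliases,
                                _stack + (expr.name,))
        negated = expr.negated ^ target.negated
        return SymbolExpr(name=target.name, args=target.args + args,
                          negated=negated)
    return SymbolExpr(name=expr.name, args=args, negated=expr.negated)


def alias_cycles(aliases: dict[str, SymbolExpr]) -> list[list[str]]:
    """Detect cycles in the alias reference graph (for validation)."""
    graph = {k: sorted(v.referenced_names() & aliases.keys())
             for k, v in aliases.items()}
    cycles: list[list[str]] = []
    seen_in_cycle: set[str] = set()

    def visit(node: str, path: list[str], on_path: set[str]) -> None:
        if node in on_path:
            cyc = path[path.index(node):] + [node]
            if not set(cyc) <= seen_in_cycle:
                cycles.append(cyc)
                seen_in_cycle.update(cyc)
            return
        on_path.add(node)
        path.append(node)
        for nxt in graph.get(node, ()):
            visit(nxt, path, on_path)
        path.pop()
        on_path.discard(node)

    for name in sorted(graph):
        visit(name, [], set())
    return cycles
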