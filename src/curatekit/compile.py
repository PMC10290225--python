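"""Compile a validated recipe into an executable template.

Compilation resolves every symbol to a callable with its literal
arguments bound (currying), builds short-circuit conjunctions or
disjunctions over the ordered condition list, and swaps the
action/counteraction sequences when ``act_on_success = false``.  It is
pure: no filesystem path is touched until execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .aggregate import REDUCERS, AggregatorSpec, Reducer
from .errors import CompileError
from .recipe import GlobalConfig, RecipeDocument, RuleSpec, validate_document
from .registry import Registry, default_registry
from .symbols import COMBINATORS, SymbolExpr, expand_aliases


@dataclass(frozen=True)
class CompiledRule:
    """Predicate plus ordered success/failure action sequences."""

    scope_label: str
    predicate: Callable                 # (ctx, node) -> bool
    on_success: tuple[Callable, ...]    # each (ctx, node) -> verdict | None
    on_failure: tuple[Callable, ...]
    counts_failures: bool               # no authored counteractions


@dataclass(frozen=True)
class CompiledAggregator:
    spec: AggregatorSpec
    filter: Callable                    # (ctx, node) -> bool
    reducer: Reducer


@dataclass(frozen=True)
class CompiledTemplate:
    config: GlobalConfig
    by_level: dict[int, CompiledRule]
    fallback: CompiledRule | None
    aggregators: tuple[CompiledAggregator, ...]
    base_dir: Path


def compile_template(doc: RecipeDocument,
                     registry: Registry | None = None) -> CompiledTemplate:
    """Resolve every symbol and build the executable template.

    Raises :class:`CompileError` listing all diagnostics if the
    document does not validate (fail closed: no partial templates).
    """
    registry = registry or default_registry()
    diagnostics = validate_document(doc, registry)
    if diagnostics:
        listing = "; ".join(str(d) for d in diagnostics)
        raise CompileError(f"recipe does not validate: {listing}",
                           diagnostics=diagnostics)

    aliases = doc.global_config.shared_map
    by_level: dict[int, CompiledRule] = {}
    fallback: CompiledRule | None = None
    for rule in doc.rules:
        compiled = _compile_rule(rule, doc.global_config, registry, aliases)
        if rule.scope.kind == "any":
            fallback = compiled
        else:
            by_level[rule.scope.level] = compiled

    aggregators = tuple(
        CompiledAggregator(
            spec=agg,
            filter=_compile_condition(expand_aliases(agg.filter, aliases),
                                      registry),
            reducer=REDUCERS[agg.reducer])
        for agg in doc.global_config.aggregators)

    return CompiledTemplate(config=doc.global_config, by_level=by_level,
                            fallback=fallback, aggregators=aggregators,
                            base_dir=Path(doc.base_dir))


def _compile_rule(rule: RuleSpec, config: GlobalConfig, registry: Registry,
                  aliases: dict[str, SymbolExpr]) -> CompiledRule:
    conditions = [
        _compile_condition(expand_aliases(e, aliases), registry)
        for e in rule.conditions]
    if rule.condition_mode == "all":
        def predicate(ctx, node, _conds=tuple(conditions)):
            return all(c(ctx, node) for c in _conds)
    else:
        def predicate(ctx, node, _conds=tuple(conditions)):
            return any(c(ctx, node) for c in _conds)

    actions = tuple(_compile_action(expand_aliases(e, aliases), registry)
                    for e in rule.actions)
    counteractions = tuple(
        _compile_action(expand_aliases(e, aliases), registry)
        for e in rule.counteractions)
    on_success, on_failure = actions, counteractions
    if not config.act_on_success:
        on_success, on_failure = on_failure, on_success
    return CompiledRule(scope_label=rule.scope.label(), predicate=predicate,
                        on_success=on_success, on_failure=on_failure,
                        counts_failures=not rule.counteractions)


def _compile_condition(expr: SymbolExpr, registry: Registry) -> Callable:
    if expr.name in COMBINATORS:
        subs = tuple(_compile_condition(a, registry) for a in expr.args)
        if expr.name == "not":
            inner = subs[0]

            def func(ctx, node):
                return not inner(ctx, node)
        elif expr.name == "all_of":
            def func(ctx, node, _subs=subs):
                return all(s(ctx, node) for s in _subs)
        else:
            def func(ctx, node, _subs=subs):
                return any(s(ctx, node) for s in _subs)
    else:
        entry = registry.lookup("condition", expr.name)
        if entry is None:  # unreachable after validation; fail closed
            raise CompileError(f"unresolved condition {expr.name!r}")
        raw, args, contain_all = entry.func, expr.args, entry.user

        def func(ctx, node, _raw=raw, _args=args, _contain=contain_all,
                 _name=expr.name):
            try:
                return bool(_raw(ctx, node, *_args))
            except FileNotFoundError:
                ctx.journal("warn", node, f"{_name}: path vanished")
                return False
            except Exception as exc:
                if not _contain:
                    raise
                ctx.journal("warn", node, f"{_name} raised: {exc}")
                return False

    if expr.negated:
        positive = func

        def func(ctx, node):  # noqa: F811 — deliberate wrap
            return not positive(ctx, node)
    return func


def _compile_action(expr: SymbolExpr, registry: Registry) -> Callable:
    entry = registry.lookup("action", expr.name)
    if entry is None:  # unreachable after validation; fail closed
        raise CompileError(f"unresolved action {expr.name!r}")
    raw, args = entry.func, expr.args

    def func(ctx, node, _raw=raw, _args=args):
        return _raw(ctx, node, *_args)

    func.symbol_name = expr.name  # type: ignore[attr-defined]
    func.is_user = entry.user     # type: ignore[attr-defined]
    return func
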