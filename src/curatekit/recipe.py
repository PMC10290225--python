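"""Parsing, validation and canonical serialization of TOML recipes.

The dialect
-----------

A recipe has a ``[global]`` table and an optional ``[template]`` table::

    [global]
    input_root = "data"
    traversal_order = "topdown"     # or "bottomup"
    parallel = false
    workers = 4
    act_on_success = true           # false: actions fire on failing nodes
    regex_enabled = false           # name_matches patterns become regexes
    destructive_allowed = false     # allow true deletion (with CLI opt-in)

    [global.shared_definitions]     # reusable aliases, expanded at compile
    is_picture = ["any_of", ["has_extension", ".tif"], ["has_extension", ".png"]]

    [[global.aggregators]]
    name = "file_count"
    filter = "is_file"
    map = "path"
    reduce = "count"
    sink = "stdout"

    [template.any]                  # applies at every depth without a
    conditions = ["is_file"]        # more specific level block
    condition_mode = "all"          # or "any"
    actions = ["show"]
    counteractions = ["warn"]

    [template.level_2]              # applies only to nodes at depth 2
    conditions = [["has_extension", ".csv"]]
    actions = [["log_to_file", "found_csv.txt"]]

Unrecognized keys are hard errors: a recipe is a contract, and a silent
typo would void it.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

from .aggregate import (MAPPERS, REDUCERS, SINK_KINDS, AggregatorSpec,
                        SinkSpec)
from .errors import RecipeError
from .registry import COMBINATOR_SIGNATURES, Registry, default_registry
from .symbols import (COMBINATORS, SymbolExpr, alias_cycles, expand_aliases,
                      parse_symbol, serialize_symbol)

TRAVERSAL_ORDERS = ("topdown", "bottomup")
CONDITION_MODES = ("all", "any")

_GLOBAL_KEYS = {
    "input_root", "traversal_order", "parallel", "workers",
    "act_on_success", "regex_enabled", "destructive_allowed",
    "quarantine_dir", "shared_definitions", "aggregators",
}
_AGGREGATOR_KEYS = {"name", "filter", "map", "reduce", "sink", "sort_key",
                    "threshold_a", "threshold_b"}
_RULE_KEYS = {"conditions", "condition_mode", "actions", "counteractions"}


@dataclass(frozen=True)
class Scope:
    """Where a rule applies: every depth ("any") or one depth ("level")."""

    kind: str                   # "any" | "level"
    level: int | None = None

    def label(self) -> str:
        return "any" if self.kind == "any" else f"level_{self.level}"


@dataclass(frozen=True)
class RuleSpec:
    scope: Scope
    conditions: tuple[SymbolExpr, ...]
    condition_mode: str = "all"
    actions: tuple[SymbolExpr, ...] = ()
    counteractions: tuple[SymbolExpr, ...] = ()


@dataclass(frozen=True)
class GlobalConfig:
    input_root: str
    traversal_order: str = "topdown"
    parallel: bool = False
    workers: int = 4
    act_on_success: bool = True
    regex_enabled: bool = False
    destructive_allowed: bool = False
    quarantine_dir: str | None = None
    shared_definitions: tuple[tuple[str, SymbolExpr], ...] = ()
    aggregators: tuple[AggregatorSpec, ...] = ()

    @property
    def shared_map(self) -> dict[str, SymbolExpr]:
        return dict(self.shared_definitions)


@dataclass(frozen=True)
class RecipeDocument:
    global_config: GlobalConfig
    rules: tuple[RuleSpec, ...] = ()
    base_dir: Path = field(default_factory=Path, compare=False)
    source_locations: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class Diagnostic:
    """One semantic problem found by :func:`validate_document`."""

    kind: str                   # unknown_symbol / arity / alias_cycle / ...
    message: str
    keypath: str = ""
    suggestion: str | None = None

    def __str__(self) -> str:
        extra = f" (did you mean {self.suggestion!r}?)" if self.suggestion else ""
        where = f" [{self.keypath}]" if self.keypath else ""
        return f"{self.kind}: {self.message}{extra}{where}"


# ---------------------------------------------------------------------------
# parsing


def parse_recipe(toml_text: str, base_dir: Path | str = ".") -> RecipeDocument:
    """Parse recipe text into a :class:`RecipeDocument`.

    Raises :class:`RecipeError` on TOML syntax errors, unrecognized
    keys, a missing ``input_root``, or a recipe that declares neither
    rules nor aggregators.
    """
    try:
        data = tomllib.loads(toml_text)
    except tomllib.TOMLDecodeError as exc:
        raise RecipeError(f"TOML syntax error: {exc}") from exc

    locations: dict[str, tuple[int, str]] = {}

    def locate(key: str, keypath: str) -> None:
        line = _find_line(toml_text, key)
        if line is not None:
            locations[keypath] = (line, keypath)

    _check_keys(data, {"global", "template"}, "", toml_text)
    if "global" not in data or not isinstance(data["global"], dict):
        raise RecipeError("missing [global] section")
    gtab = data["global"]
    _check_keys(gtab, _GLOBAL_KEYS, "global", toml_text)

    input_root = gtab.get("input_root")
    if not isinstance(input_root, str) or not input_root:
        raise RecipeError("missing input_root", keypath="global.input_root",
                          line=_find_line(toml_text, "input_root"))
    locate("input_root", "global.input_root")

    order = _expect(gtab, "traversal_order", str, "topdown", toml_text)
    if order not in TRAVERSAL_ORDERS:
        raise RecipeError(
            f"traversal_order must be one of {TRAVERSAL_ORDERS}, got {order!r}",
            keypath="global.traversal_order")

    shared: list[tuple[str, SymbolExpr]] = []
    for alias, value in gtab.get("shared_definitions", {}).items():
        shared.append((alias, parse_symbol(
            value, keypath=f"global.shared_definitions.{alias}")))

    aggregators = tuple(
        _parse_aggregator(tab, i, toml_text)
        for i, tab in enumerate(_expect(gtab, "aggregators", list, [],
                                        toml_text)))

    config = GlobalConfig(
        input_root=input_root,
        traversal_order=order,
        parallel=_expect(gtab, "parallel", bool, False, toml_text),
        workers=_expect(gtab, "workers", int, 4, toml_text),
        act_on_success=_expect(gtab, "act_on_success", bool, True, toml_text),
        regex_enabled=_expect(gtab, "regex_enabled", bool, False, toml_text),
        destructive_allowed=_expect(gtab, "destructive_allowed", bool, False,
                                    toml_text),
        quarantine_dir=gtab.get("quarantine_dir"),
        shared_definitions=tuple(shared),
        aggregators=aggregators,
    )

    rules: list[RuleSpec] = []
    template = data.get("template", {})
    if not isinstance(template, dict):
        raise RecipeError("[template] must be a table of rule blocks")
    seen_scopes: set[str] = set()
    for scope_key, block in template.items():
        scope = _parse_scope(scope_key, toml_text)
        if scope.label() in seen_scopes:
            raise RecipeError(f"duplicate rule block for scope {scope_key!r}",
                              keypath=f"template.{scope_key}")
        seen_scopes.add(scope.label())
        rules.append(_parse_rule(scope, block, toml_text))
        locate(scope_key, f"template.{scope_key}")

    if not rules and not aggregators:
        raise RecipeError("at least one rule or aggregator required")

    return RecipeDocument(global_config=config, rules=tuple(rules),
                          base_dir=Path(base_dir),
                          source_locations=locations)


def load_recipe(path: Path | str) -> RecipeDocument:
    """Read a recipe file; relative paths inside it resolve against its
    own directory."""
    path = Path(path)
    return parse_recipe(path.read_text(encoding="utf-8"),
                        base_dir=path.parent)


def _parse_scope(scope_key: str, text: str) -> Scope:
    if scope_key == "any":
        return Scope("any")
    if scope_key.startswith("level_"):
        tail = scope_key[len("level_"):]
        try:
            level = int(tail)
        except ValueError:
            raise RecipeError(
                f"bad scope {scope_key!r}: expected 'any' or 'level_<k>'",
                keypath=f"template.{scope_key}",
                line=_find_line(text, scope_key)) from None
        return Scope("level", level)
    raise RecipeError(
        f"unknown rule scope {scope_key!r}: expected 'any' or 'level_<k>'",
        keypath=f"template.{scope_key}", line=_find_line(text, scope_key))


def _parse_rule(scope: Scope, block, text: str) -> RuleSpec:
    keypath = f"template.{scope.label()}"
    if not isinstance(block, dict):
        raise RecipeError(f"rule block must be a table", keypath=keypath)
    _check_keys(block, _RULE_KEYS, keypath, text)
    mode = block.get("condition_mode", "all")
    if mode not in CONDITION_MODES:
        raise RecipeError(
            f"condition_mode must be one of {CONDITION_MODES}, got {mode!r}",
            keypath=keypath)

    def symbols(key: str) -> tuple[SymbolExpr, ...]:
        raw = block.get(key, [])
        if not isinstance(raw, list):
            raise RecipeError(f"{key} must be an array",
                              keypath=f"{keypath}.{key}")
        return tuple(parse_symbol(v, keypath=f"{keypath}.{key}[{i}]")
                     for i, v in enumerate(raw))

    return RuleSpec(scope=scope, conditions=symbols("conditions"),
                    condition_mode=mode, actions=symbols("actions"),
                    counteractions=symbols("counteractions"))


def _parse_aggregator(tab, index: int, text: str) -> AggregatorSpec:
    keypath = f"global.aggregators[{index}]"
    if not isinstance(tab, dict):
        raise RecipeError("aggregator must be a table", keypath=keypath)
    _check_keys(tab, _AGGREGATOR_KEYS, keypath, text)
    name = tab.get("name")
    if not isinstance(name, str) or not name:
        raise RecipeError("aggregator needs a name", keypath=keypath)
    sink = _parse_sink(tab.get("sink", "stdout"), f"{keypath}.sink", text)
    return AggregatorSpec(
        name=name,
        filter=parse_symbol(tab.get("filter", "always"),
                            keypath=f"{keypath}.filter"),
        mapper=tab.get("map", "path"),
        reducer=tab.get("reduce", ""),
        sink=sink,
        sort_key=tab.get("sort_key"),
        threshold_a=float(tab.get("threshold_a", 0.0)),
        threshold_b=float(tab.get("threshold_b", 0.0)),
    )


def _parse_sink(value, keypath: str, text: str) -> SinkSpec:
    if value == "stdout":
        return SinkSpec("stdout", None)
    if isinstance(value, dict):
        _check_keys(value, {"kind", "destination"}, keypath, text)
        kind = value.get("kind", "stdout")
        return SinkSpec(kind, value.get("destination"))
    raise RecipeError(
        'sink must be "stdout" or {kind=..., destination=...}',
        keypath=keypath)


def _check_keys(table: dict, allowed: set[str], keypath: str,
                text: str) -> None:
    for key in table:
        if key not in allowed:
            where = f"{keypath}.{key}" if keypath else key
            raise RecipeError(f"unknown key {key!r}", keypath=where,
                              line=_find_line(text, key))


def _expect(table: dict, key: str, typ, default, text: str):
    value = table.get(key, default)
    if not isinstance(value, typ) or (typ is int and isinstance(value, bool)):
        raise RecipeError(
            f"{key} must be of type {typ.__name__}",
            keypath=f"global.{key}", line=_find_line(text, key))
    return value


def _find_line(text: str, token: str) -> int | None:
    # best effort: TOML loading does not retain positions for valid keys
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0]
        if token in stripped:
            return i
    return None


# ---------------------------------------------------------------------------
# validation


def validate_document(doc: RecipeDocument,
                      registry: Registry | None = None) -> list[Diagnostic]:
    """Collect every semantic problem; an empty list means compilable."""
    registry = registry or default_registry()
    diags: list[Diagnostic] = []
    aliases = doc.global_config.shared_map

    for cycle in alias_cycles(aliases):
        diags.append(Diagnostic(
            "alias_cycle", "shared definitions form a cycle: "
            + " -> ".join(cycle), keypath="global.shared_definitions"))
    cyclic = {name for cycle in alias_cycles(aliases) for name in cycle}
    safe_aliases = {k: v for k, v in aliases.items() if k not in cyclic}

    agg_names: list[str] = []
    for i, agg in enumerate(doc.global_config.aggregators):
        keypath = f"global.aggregators[{i}]"
        if agg.name in agg_names:
            diags.append(Diagnostic(
                "duplicate_aggregator", f"duplicate name {agg.name!r}",
                keypath=keypath))
        agg_names.append(agg.name)
        _check_symbol(agg.filter, "condition", registry, safe_aliases,
                      f"{keypath}.filter", diags)
        if agg.mapper not in MAPPERS:
            diags.append(Diagnostic(
                "unknown_mapper", f"unknown mapper {agg.mapper!r}",
                keypath=f"{keypath}.map",
                suggestion=_nearest(agg.mapper, MAPPERS)))
        if agg.reducer not in REDUCERS:
            diags.append(Diagnostic(
                "unknown_reducer", f"unknown reducer {agg.reducer!r}",
                keypath=f"{keypath}.reduce",
                suggestion=_nearest(agg.reducer, REDUCERS)))
        elif agg.mapper in MAPPERS:
            reducer = REDUCERS[agg.reducer]
            elem_type = MAPPERS[agg.mapper][1]
            if not reducer.accepts(elem_type):
                diags.append(Diagnostic(
                    "type_mismatch",
                    f"reducer {agg.reducer!r} cannot consume "
                    f"{elem_type!r} elements produced by map={agg.mapper!r}",
                    keypath=keypath))
        if agg.sink.kind not in SINK_KINDS:
            diags.append(Diagnostic(
                "unknown_sink", f"unknown sink kind {agg.sink.kind!r}",
                keypath=f"{keypath}.sink"))
        elif agg.sink.kind != "stdout" and not agg.sink.destination:
            diags.append(Diagnostic(
                "missing_destination",
                f"sink kind {agg.sink.kind!r} needs a destination",
                keypath=f"{keypath}.sink"))

    for rule in doc.rules:
        keypath = f"template.{rule.scope.label()}"
        if rule.scope.kind == "level" and (rule.scope.level is None
                                           or rule.scope.level < 1):
            diags.append(Diagnostic(
                "bad_level", f"level must be >= 1, got {rule.scope.level}",
                keypath=keypath))
        if not rule.conditions:
            kind = ("counteractions_without_conditions"
                    if rule.counteractions else "missing_conditions")
            diags.append(Diagnostic(
                kind, "rule declares no conditions", keypath=keypath))
        for j, expr in enumerate(rule.conditions):
            _check_symbol(expr, "condition", registry, safe_aliases,
                          f"{keypath}.conditions[{j}]", diags)
        for key, exprs in (("actions", rule.actions),
                           ("counteractions", rule.counteractions)):
            for j, expr in enumerate(exprs):
                _check_symbol(expr, "action", registry, safe_aliases,
                              f"{keypath}.{key}[{j}]", diags,
                              aggregator_names=agg_names)
    return diags


def _check_symbol(expr: SymbolExpr, role: str, registry: Registry,
                  aliases: dict[str, SymbolExpr], keypath: str,
                  diags: list[Diagnostic],
                  aggregator_names: list[str] | None = None) -> None:
    try:
        expr = expand_aliases(expr, aliases)
    except RecipeError:
        return  # cycle already reported
    _check_expanded(expr, role, registry, keypath, diags, aggregator_names)


def _check_expanded(expr: SymbolExpr, role: str, registry: Registry,
                    keypath: str, diags: list[Diagnostic],
                    aggregator_names: list[str] | None) -> None:
    if expr.name in COMBINATORS:
        if role != "condition":
            diags.append(Diagnostic(
                "combinator_as_action",
                f"{expr.name!r} combines conditions, not actions",
                keypath=keypath))
            return
        sig = COMBINATOR_SIGNATURES[expr.name]
        nested = [a for a in expr.args if isinstance(a, SymbolExpr)]
        if len(nested) != len(expr.args):
            diags.append(Diagnostic(
                "arity", f"{expr.name!r} takes condition expressions only",
                keypath=keypath))
        if expr.name == "not" and len(nested) != 1:
            diags.append(Diagnostic(
                "arity", "'not' takes exactly one expression",
                keypath=keypath))
        elif expr.name != "not" and not nested:
            diags.append(Diagnostic(
                "arity", f"{expr.name!r} needs at least one expression",
                keypath=keypath))
        for sub in nested:
            _check_expanded(sub, role, registry, keypath, diags,
                            aggregator_names)
        return
    entry = registry.lookup(role, expr.name)
    if entry is None:
        diags.append(Diagnostic(
            "unknown_symbol", f"unknown {role} {expr.name!r}",
            keypath=keypath,
            suggestion=_nearest(expr.name, registry.names(role))))
        return
    for problem in entry.signature.check(expr.args):
        diags.append(Diagnostic(
            "arity", f"{expr.name}: {problem}", keypath=keypath))
    if (expr.name in ("add_to_list", "add_to_aggregator")
            and aggregator_names is not None and expr.args
            and isinstance(expr.args[0], str)
            and expr.args[0] not in aggregator_names):
        diags.append(Diagnostic(
            "unknown_aggregator",
            f"{expr.name} targets undeclared aggregator {expr.args[0]!r}",
            keypath=keypath,
            suggestion=_nearest(expr.args[0], aggregator_names)))


def _nearest(name: str, candidates) -> str | None:
    import difflib

    matches = difflib.get_close_matches(name, list(candidates), n=1)
    return matches[0] if matches else None


# ---------------------------------------------------------------------------
# canonical serialization


def serialize_document(doc: RecipeDocument) -> str:
    """Emit the canonical TOML form; reparsing yields an equal document."""
    cfg = doc.global_config
    lines = ["[global]"]
    lines.append(f"input_root = {_toml_value(cfg.input_root)}")
    lines.append(f"traversal_order = {_toml_value(cfg.traversal_order)}")
    lines.append(f"parallel = {_toml_value(cfg.parallel)}")
    lines.append(f"workers = {_toml_value(cfg.workers)}")
    lines.append(f"act_on_success = {_toml_value(cfg.act_on_success)}")
    lines.append(f"regex_enabled = {_toml_value(cfg.regex_enabled)}")
    lines.append(
        f"destructive_allowed = {_toml_value(cfg.destructive_allowed)}")
    if cfg.quarantine_dir is not None:
        lines.append(f"quarantine_dir = {_toml_value(cfg.quarantine_dir)}")
    if cfg.shared_definitions:
        lines.append("")
        lines.append("[global.shared_definitions]")
        for alias, expr in cfg.shared_definitions:
            lines.append(
                f"{alias} = {_toml_value(serialize_symbol(expr))}")
    for agg in cfg.aggregators:
        lines.append("")
        lines.append("[[global.aggregators]]")
        lines.append(f"name = {_toml_value(agg.name)}")
        lines.append(f"filter = {_toml_value(serialize_symbol(agg.filter))}")
        lines.append(f"map = {_toml_value(agg.mapper)}")
        lines.append(f"reduce = {_toml_value(agg.reducer)}")
        if agg.sink.kind == "stdout":
            lines.append('sink = "stdout"')
        else:
            lines.append(
                "sink = { kind = %s, destination = %s }"
                % (_toml_value(agg.sink.kind),
                   _toml_value(agg.sink.destination)))
        if agg.sort_key is not None:
            lines.append(f"sort_key = {_toml_value(agg.sort_key)}")
        if agg.threshold_a:
            lines.append(f"threshold_a = {_toml_value(agg.threshold_a)}")
        if agg.threshold_b:
            lines.append(f"threshold_b = {_toml_value(agg.threshold_b)}")
    for rule in doc.rules:
        lines.append("")
        lines.append(f"[template.{rule.scope.label()}]")
        lines.append("conditions = " + _toml_value(
            [serialize_symbol(e) for e in rule.conditions]))
        lines.append(f"condition_mode = {_toml_value(rule.condition_mode)}")
        if rule.actions:
            lines.append("actions = " + _toml_value(
                [serialize_symbol(e) for e in rule.actions]))
        if rule.counteractions:
            lines.append("counteractions = " + _toml_value(
                [serialize_symbol(e) for e in rule.counteractions]))
    return "\n".join(lines) + "\n"


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        escaped = value.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    if isinstance(value, list):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value).__name__}")
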