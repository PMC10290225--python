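"""The symbol registry: built-in conditions, actions and combinators,
plus user extension.

Conditions are predicates over a visited node; they never mutate the
filesystem.  Actions may mutate (copy/move/rename/quarantine) and every
mutating action journals exactly one effect record; in dry-run mode the
effect is journaled but not applied.

Callables follow one convention::

    condition(ctx, node, *literal_args) -> bool
    action(ctx, node, *literal_args)    -> None | "quit" | "quit_on_fail"

where ``ctx`` is the worker-local execution context (see
:mod:`curatekit.engine`) and ``node`` the visited entry.
"""

from __future__ import annotations

import os
import re
import shutil
from dataclasses import dataclass, field
from typing import Callable

from .errors import ExecutionError, RegistryError
from .io_utils import (IMAGE_EXTENSIONS, claim_destination, csv_header,
                       is_image_path, load_image)
from .symbols import COMBINATORS, SymbolExpr

# ---------------------------------------------------------------------------
# signatures

#: argument kinds a signature may declare
ARG_KINDS = ("str", "int", "number", "transform")


@dataclass(frozen=True)
class Signature:
    """Declared arity and argument kinds of a registry symbol.

    ``params`` are the fixed leading arguments; ``variadic`` (if set)
    is the kind accepted for any number of trailing arguments, of which
    at least ``min_variadic`` must be present.
    """

    params: tuple[str, ...] = ()
    variadic: str | None = None
    min_variadic: int = 0

    def check(self, args: tuple) -> list[str]:
        """Return human-readable problems with ``args`` (empty = fine)."""
        problems = []
        nfixed = len(self.params)
        if self.variadic is None and len(args) != nfixed:
            problems.append(f"expects {nfixed} argument(s), got {len(args)}")
            return problems
        if len(args) < nfixed + self.min_variadic:
            problems.append(
                f"expects at least {nfixed + self.min_variadic} "
                f"argument(s), got {len(args)}")
            return problems
        kinds = list(self.params) + [self.variadic] * (len(args) - nfixed)
        for i, (kind, arg) in enumerate(zip(kinds, args), start=1):
            err = _check_kind(kind, arg)
            if err:
                problems.append(f"argument {i} {err}")
        return problems


def _check_kind(kind: str, arg) -> str | None:
    if kind == "str":
        return None if isinstance(arg, str) else "must be a string"
    if kind == "int":
        if isinstance(arg, bool) or not isinstance(arg, int):
            return "must be an integer"
        return None
    if kind == "number":
        if isinstance(arg, bool) or not isinstance(arg, (int, float)):
            return "must be a number"
        return None
    if kind == "transform":
        if isinstance(arg, str):
            return (None if arg in RENAME_TRANSFORMS
                    else f"unknown rename transform {arg!r}")
        if isinstance(arg, SymbolExpr):
            if arg.name != "strip_prefix":
                return f"unknown rename transform {arg.name!r}"
            if len(arg.args) != 1 or not isinstance(arg.args[0], str):
                return "strip_prefix takes one string argument"
            return None
        return "must be a transform name"
    raise AssertionError(f"unknown arg kind {kind}")


@dataclass(frozen=True)
class RegistryEntry:
    func: Callable
    signature: Signature
    user: bool = False
    doc: str = ""


@dataclass
class Registry:
    """Role-aware name → callable maps.

    A name is looked up as a condition or as an action depending on its
    position in the rule, so the two namespaces may overlap.
    """

    conditions: dict[str, RegistryEntry] = field(default_factory=dict)
    actions: dict[str, RegistryEntry] = field(default_factory=dict)

    def lookup(self, role: str, name: str) -> RegistryEntry | None:
        return self._table(role).get(name)

    def names(self, role: str) -> list[str]:
        return sorted(self._table(role))

    def _table(self, role: str) -> dict[str, RegistryEntry]:
        if role == "condition":
            return self.conditions
        if role == "action":
            return self.actions
        raise ValueError(f"unknown role {role!r}")


@dataclass(frozen=True)
class ActionEffect:
    """One journaled effect of an action on one node."""

    walk_index: int
    seq: int                    # order within the node's action list
    path: str                   # node path relative to the input root
    rule_scope: str             # "any", "level_3", "aggregator", "run"
    kind: str                   # log/copy/move/rename/quarantine/delete/...
    detail: str = ""

    def sort_key(self) -> tuple:
        return (self.walk_index, self.seq, self.kind, self.path, self.detail)


# ---------------------------------------------------------------------------
# built-in conditions


def _cond_is_file(ctx, node):
    return node.kind == "file"


def _cond_is_dir(ctx, node):
    return node.kind == "directory"


def _cond_is_hidden(ctx, node):
    return node.path.name.startswith(".")


def _cond_has_extension(ctx, node, ext):
    ext = ext if ext.startswith(".") else "." + ext
    return node.path.suffix.lower() == ext.lower()


def _cond_name_matches(ctx, node, pattern):
    # regex iff the recipe enables it; otherwise an exact literal match
    if ctx.run.config.regex_enabled:
        return re.fullmatch(pattern, node.path.name) is not None
    return node.path.name == pattern


def _cond_name_is_integer(ctx, node):
    stem = node.path.stem if node.kind == "file" else node.path.name
    return stem.isdigit()


def _cond_size_at_least(ctx, node, n):
    if node.kind != "file":
        return False
    return node.path.stat().st_size >= n


def _cond_size_at_most(ctx, node, n):
    if node.kind != "file":
        return False
    return node.path.stat().st_size <= n


def _cond_is_image(ctx, node):
    return node.kind == "file" and is_image_path(node.path)


def _cond_image_has_dims(ctx, node, n):
    if not _cond_is_image(ctx, node):
        return False
    try:
        return load_image(node.path).ndim == n
    except Exception:
        return False


def _cond_is_csv(ctx, node):
    return node.kind == "file" and node.path.suffix.lower() == ".csv"


def _cond_csv_has_columns(ctx, node, *cols):
    if not _cond_is_csv(ctx, node):
        return False
    try:
        header = csv_header(node.path)
    except Exception:
        return False
    return set(cols) <= set(header)


def _cond_path_depth_is(ctx, node, k):
    return node.depth == k


def _cond_always(ctx, node):
    return True


def _cond_never(ctx, node):
    return False


_BUILTIN_CONDITIONS = {
    "is_file": (_cond_is_file, Signature()),
    "is_dir": (_cond_is_dir, Signature()),
    "is_hidden": (_cond_is_hidden, Signature()),
    "has_extension": (_cond_has_extension, Signature(("str",))),
    "name_matches": (_cond_name_matches, Signature(("str",))),
    "name_is_integer": (_cond_name_is_integer, Signature()),
    "size_at_least": (_cond_size_at_least, Signature(("int",))),
    "size_at_most": (_cond_size_at_most, Signature(("int",))),
    "is_image": (_cond_is_image, Signature()),
    "image_has_dims": (_cond_image_has_dims, Signature(("int",))),
    "is_csv": (_cond_is_csv, Signature()),
    "csv_has_columns": (_cond_csv_has_columns,
                        Signature(variadic="str", min_variadic=1)),
    "path_depth_is": (_cond_path_depth_is, Signature(("int",))),
    "always": (_cond_always, Signature()),
    "never": (_cond_never, Signature()),
}

#: combinator arity validated structurally during recipe validation
COMBINATOR_SIGNATURES = {
    "all_of": Signature(variadic="expr", min_variadic=1),
    "any_of": Signature(variadic="expr", min_variadic=1),
    "not": Signature(params=("expr",)),
}


# ---------------------------------------------------------------------------
# rename transforms


def _tf_whitespace_to_underscore(name: str) -> str:
    return re.sub(r"\s+", "_", name)


def _tf_to_lowercase(name: str) -> str:
    return name.lower()


RENAME_TRANSFORMS: dict[str, Callable[[str], str]] = {
    "whitespace_to_underscore": _tf_whitespace_to_underscore,
    "to_lowercase": _tf_to_lowercase,
}


def _apply_transform(name: str, transform) -> str:
    if isinstance(transform, str):
        return RENAME_TRANSFORMS[transform](name)
    # strip_prefix(s) arrives as a nested symbol expression
    prefix = transform.args[0]
    return name[len(prefix):] if name.startswith(prefix) else name


# ---------------------------------------------------------------------------
# built-in actions


def _act_warn(ctx, node):
    ctx.journal("warn", node, "condition outcome flagged")


def _act_show(ctx, node):
    ctx.journal("show", node, "")


def _act_log_to_file(ctx, node, dest):
    ctx.add_log_line(dest, ctx.relpath(node))
    ctx.journal("log", node, f"-> {dest}")


def _resolve_dir(ctx, dirname: str):
    from pathlib import Path

    p = Path(dirname)
    return p if p.is_absolute() else ctx.run.base_dir / p


def _act_copy_to(ctx, node, dirname):
    dest = _resolve_dir(ctx, dirname) / node.path.name
    _transfer(ctx, node, dest, move=False, kind="copy")


def _act_move_to(ctx, node, dirname):
    dest = _resolve_dir(ctx, dirname) / node.path.name
    _transfer(ctx, node, dest, move=True, kind="move")


def _act_flatten_to(ctx, node, dirname):
    # path-derived unique name: relative components joined by "_"
    rel = ctx.relpath(node)
    flat = "_".join(rel.split("/"))
    dest = _resolve_dir(ctx, dirname) / flat
    _transfer(ctx, node, dest, move=False, kind="copy")


def _transfer(ctx, node, dest, *, move: bool, kind: str) -> None:
    if not node.path.exists():
        ctx.journal("warn", node, f"{kind} skipped: source vanished")
        return
    if ctx.run.dry_run:
        ctx.journal(kind, node, f"-> {ctx.rel_display(dest)} (dry-run)")
        return
    try:
        claimed = claim_destination(dest)
        if node.kind == "directory":
            os.unlink(claimed)  # placeholder; directories copied whole
            if move:
                shutil.move(str(node.path), str(claimed))
            else:
                shutil.copytree(str(node.path), str(claimed))
        elif move:
            os.replace(str(node.path), str(claimed))
        else:
            shutil.copyfile(str(node.path), str(claimed))
    except OSError as exc:
        raise ExecutionError(
            f"action {kind}_to failed on {node.path}: {exc}") from exc
    ctx.journal(kind, node, f"-> {ctx.rel_display(claimed)}")


def _act_remove(ctx, node):
    """Quarantine by default; true deletion needs recipe AND run opt-in."""
    destructive = (ctx.run.config.destructive_allowed
                   and ctx.run.allow_destructive)
    if not node.path.exists():
        ctx.journal("warn", node, "remove skipped: vanished")
        return
    if ctx.run.dry_run:
        kind = "delete" if destructive else "quarantine"
        ctx.journal(kind, node, "(dry-run)")
        return
    if destructive:
        try:
            if node.kind == "directory":
                shutil.rmtree(str(node.path))
            else:
                os.unlink(str(node.path))
        except OSError as exc:
            raise ExecutionError(
                f"action remove failed on {node.path}: {exc}") from exc
        ctx.journal("delete", node, "")
        return
    rel = ctx.relpath(node)
    dest = ctx.run.quarantine_dir / rel
    try:
        claimed = claim_destination(dest)
        os.replace(str(node.path), str(claimed))
    except OSError as exc:
        raise ExecutionError(
            f"action remove failed on {node.path}: {exc}") from exc
    ctx.journal("quarantine", node, f"-> {ctx.rel_display(claimed)}")


def _act_rename(ctx, node, *transforms):
    old = node.path.name
    new = old
    for t in transforms:
        new = _apply_transform(new, t)
    if new == old:
        return
    if not node.path.exists():
        ctx.journal("warn", node, "rename skipped: vanished")
        return
    dest = node.path.with_name(new)
    if ctx.run.dry_run:
        ctx.journal("rename", node, f"-> {new} (dry-run)")
        return
    try:
        claimed = claim_destination(dest)
        os.replace(str(node.path), str(claimed))
    except OSError as exc:
        raise ExecutionError(
            f"action rename failed on {node.path}: {exc}") from exc
    ctx.journal("rename", node, f"-> {claimed.name}")


def _act_add_to_list(ctx, node, name):
    ctx.add_to_aggregator(name, node)
    ctx.journal("list_add", node, f"-> {name}")


def _act_add_to_aggregator(ctx, node, name):
    ctx.add_to_aggregator(name, node)
    ctx.journal("aggregate_add", node, f"-> {name}")


def _act_quit(ctx, node):
    ctx.journal("quit", node, "")
    return "quit"


def _act_quit_on_fail(ctx, node):
    ctx.journal("quit", node, "abort")
    return "quit_on_fail"


_BUILTIN_ACTIONS = {
    "warn": (_act_warn, Signature()),
    "show": (_act_show, Signature()),
    "log_to_file": (_act_log_to_file, Signature(("str",))),
    "copy_to": (_act_copy_to, Signature(("str",))),
    "move_to": (_act_move_to, Signature(("str",))),
    "flatten_to": (_act_flatten_to, Signature(("str",))),
    "remove": (_act_remove, Signature()),
    "rename": (_act_rename, Signature(variadic="transform", min_variadic=1)),
    "add_to_list": (_act_add_to_list, Signature(("str",))),
    "add_to_aggregator": (_act_add_to_aggregator, Signature(("str",))),
    "quit": (_act_quit, Signature()),
    "quit_on_fail": (_act_quit_on_fail, Signature()),
}


# ---------------------------------------------------------------------------
# registry construction & extension


def default_registry() -> Registry:
    """A fresh registry holding every built-in symbol."""
    reg = Registry()
    for name, (func, sig) in _BUILTIN_CONDITIONS.items():
        reg.conditions[name] = RegistryEntry(func, sig,
                                             doc=(func.__doc__ or ""))
    for name, (func, sig) in _BUILTIN_ACTIONS.items():
        reg.actions[name] = RegistryEntry(func, sig, doc=(func.__doc__ or ""))
    return reg


def builtin_conditions() -> set[str]:
    return set(_BUILTIN_CONDITIONS)


def builtin_actions() -> set[str]:
    return set(_BUILTIN_ACTIONS)


def register_user_symbol(registry: Registry, role: str, name: str,
                         func: Callable,
                         signature: Signature | None = None) -> Registry:
    """Add a user condition/action, usable from recipes like a built-in.

    Shadowing a built-in (or a combinator name) is forbidden.  User
    conditions are exception-contained at execution time: a raising
    condition evaluates false and journals a warning rather than
    aborting the run.
    """
    if name in COMBINATORS:
        raise RegistryError(f"cannot shadow combinator {name!r}")
    table = registry._table(role)
    existing = table.get(name)
    if existing is not None and not existing.user:
        raise RegistryError(f"cannot shadow built-in {role} {name!r}")
    table[name] = RegistryEntry(func, signature or Signature(), user=True,
                                doc=(func.__doc__ or ""))
    return registry


def compose(op: str, exprs: list[SymbolExpr]) -> SymbolExpr:
    """Combine expressions with a logical operator (nesting allowed)."""
    if op not in COMBINATORS:
        raise ValueError(f"unknown combinator {op!r}")
    if op == "not":
        if len(exprs) != 1:
            raise ValueError("'not' takes exactly one expression")
    elif not exprs:
        raise ValueError(f"{op!r} needs at least one expression")
    return SymbolExpr(name=op, args=tuple(exprs))
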