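"""Tree traversal and rule execution.

The engine snapshots the input tree once, walks it in the configured
order (top-down or bottom-up, siblings in lexicographic byte order),
dispatches the depth-appropriate compiled rule to each node, runs
actions/counteractions left to right, and feeds every visited node to
the aggregators.

Parallel execution partitions nodes across worker threads.  Each worker
owns a private journal, private aggregator contribution lists and a
private early-exit signal list — no shared mutable state exists during
the run, so data races are impossible by construction.  Shards are
merged exactly once at completion.  Every journal entry and aggregator
contribution is tagged with the node's serial walk index; when an early
exit fires, finalization truncates at the minimal quit index, which
makes finalized aggregates and canonical journals identical to the
serial run even though in-flight nodes may have been evaluated
speculatively.
"""

from __future__ import annotations

import csv
import io
import queue
import threading
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

from .aggregate import Shard, map_node, merge_shards, write_sink
from .compile import CompiledAggregator, CompiledRule, CompiledTemplate
from .errors import ExecutionError
from .io_utils import atomic_write_text
from .registry import ActionEffect

_FINALIZE_INDEX = 10 ** 9  # journal index for end-of-run effects


@dataclass(frozen=True)
class Node:
    """One visited filesystem entry.

    The input root itself is not a node; its immediate children are at
    depth 1.
    """

    path: Path
    depth: int
    kind: str  # "file" | "directory"


@dataclass(frozen=True)
class Verdict:
    code: str = "proceed"  # "proceed" | "quit"
    rule_passed: bool = True


@dataclass
class ExecutionResult:
    status: str                       # ok/validation_failures/aborted/error
    visited_count: int
    fired: tuple[ActionEffect, ...]   # canonical (sorted) journal
    aggregates: dict[str, object]
    failure_count: int
    sink_paths: dict[str, Path | None] = field(default_factory=dict)
    quit_index: int | None = None
    error: str | None = None

    def journal_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(
            ["walk_index", "path", "rule_scope", "effect_kind", "detail"])
        for e in self.fired:
            writer.writerow(
                [e.walk_index, e.path, e.rule_scope, e.kind, e.detail])
        return buf.getvalue()


# ---------------------------------------------------------------------------
# walking


def walk(root: Path, order: str = "topdown",
         skip: frozenset = frozenset()) -> Iterator[Node]:
    """Yield every entry under ``root`` exactly once.

    ``topdown`` yields a directory before its contents, ``bottomup``
    after; sibling order is the lexicographic byte order of names in
    both cases.  Hidden entries are yielded — conditions decide
    relevance.
    """
    root = Path(root)
    if not root.is_dir():
        raise ExecutionError(f"input root {root} is not a directory")
    if order not in ("topdown", "bottomup"):
        raise ExecutionError(f"unknown traversal order {order!r}")
    yield from _walk(root, 1, order, skip)


def _walk(directory: Path, depth: int, order: str,
          skip: frozenset) -> Iterator[Node]:
    try:
        entries = sorted(directory.iterdir(),
                         key=lambda p: p.name.encode("utf-8"))
    except FileNotFoundError:
        return
    for entry in entries:
        if entry in skip:
            continue
        if entry.is_dir() and not entry.is_symlink():
            node = Node(entry, depth, "directory")
            if order == "topdown":
                yield node
                yield from _walk(entry, depth + 1, order, skip)
            else:
                yield from _walk(entry, depth + 1, order, skip)
                yield node
        else:
            yield Node(entry, depth, "file")


def dispatch(template: CompiledTemplate, node: Node) -> CompiledRule | None:
    """Depth-specific rule if present, else the "any" fallback, else none."""
    rule = template.by_level.get(node.depth)
    if rule is not None:
        return rule
    return template.fallback


# ---------------------------------------------------------------------------
# execution contexts


class RunContext:
    """Run-wide immutable configuration shared (read-only) by workers."""

    def __init__(self, template: CompiledTemplate, *, dry_run: bool,
                 allow_destructive: bool,
                 action_error_policy: str = "abort") -> None:
        self.template = template
        self.config = template.config
        self.base_dir = Path(template.base_dir).resolve()
        root = Path(template.config.input_root)
        self.input_root = (root if root.is_absolute()
                           else self.base_dir / root).resolve()
        qdir = template.config.quarantine_dir
        if qdir is None:
            self.quarantine_dir = self.input_root.parent / (
                self.input_root.name + "_quarantine")
        else:
            q = Path(qdir)
            self.quarantine_dir = (q if q.is_absolute()
                                   else self.base_dir / q).resolve()
        self.dry_run = dry_run
        self.allow_destructive = allow_destructive
        self.action_error_policy = action_error_policy
        self.quit_event = threading.Event()


class WorkerContext:
    """Worker-private mutable state; only its owner writes during a run."""

    def __init__(self, run: RunContext, worker_id: int) -> None:
        self.run = run
        self.worker_id = worker_id
        self.journal_entries: list[ActionEffect] = []
        self.contributions: dict[str, list[tuple[int, object]]] = {
            agg.spec.name: [] for agg in run.template.aggregators}
        self.log_lines: dict[str, list[tuple[int, str]]] = {}
        self.failures: list[int] = []
        self.quit_signals: list[tuple[int, str]] = []
        self.visited = 0
        self.current_index = -1
        self.current_scope = ""
        self._seq = 0

    # -- journaling interface used by actions and condition wrappers

    def journal(self, kind: str, node: Node, detail: str = "") -> None:
        self.journal_entries.append(ActionEffect(
            walk_index=self.current_index, seq=self._seq,
            path=self.relpath(node), rule_scope=self.current_scope,
            kind=kind, detail=detail))
        self._seq += 1

    def add_log_line(self, dest: str, line: str) -> None:
        self.log_lines.setdefault(dest, []).append(
            (self.current_index, line))

    def add_to_aggregator(self, name: str, node: Node) -> None:
        for agg in self.run.template.aggregators:
            if agg.spec.name == name:
                elem = map_node(agg.spec, self, node)
                if elem is not None:
                    self.contributions[name].append(
                        (self.current_index, elem))
                return
        raise ExecutionError(f"no aggregator named {name!r}")

    def relpath(self, node: Node) -> str:
        try:
            return node.path.resolve().relative_to(
                self.run.input_root).as_posix()
        except ValueError:
            return node.path.as_posix()

    def rel_display(self, path: Path) -> str:
        """Journal-friendly rendering of a destination path (relative
        to the recipe directory so journals are location-independent)."""
        p = Path(path).resolve()
        for anchor in (self.run.base_dir, self.run.input_root.parent):
            try:
                return p.relative_to(anchor).as_posix()
            except ValueError:
                continue
        return p.as_posix()


# ---------------------------------------------------------------------------
# rule application


def apply_rule(rule: CompiledRule, node: Node, ctx: WorkerContext) -> Verdict:
    """Evaluate the predicate once and run the appropriate action list
    left to right; an early-exit action stops the list."""
    ctx.current_scope = rule.scope_label
    if not node.path.exists():
        ctx.journal("warn", node, "node vanished before dispatch")
        return Verdict("proceed", rule_passed=True)
    passed = rule.predicate(ctx, node)
    actions = rule.on_success if passed else rule.on_failure
    if not passed and rule.counts_failures:
        ctx.failures.append(ctx.current_index)
    code = "proceed"
    for action in actions:
        try:
            outcome = action(ctx, node)
        except ExecutionError:
            raise
        except Exception as exc:
            if getattr(action, "is_user", False):
                name = getattr(action, "symbol_name", "?")
                ctx.journal("error", node, f"user action {name} raised: {exc}")
                if ctx.run.action_error_policy == "abort":
                    raise ExecutionError(
                        f"user action {name} failed on {node.path}: {exc}"
                    ) from exc
                continue
            raise
        if outcome in ("quit", "quit_on_fail"):
            ctx.quit_signals.append((ctx.current_index, outcome))
            code = "quit"
            break
    return Verdict(code, rule_passed=passed)


def _process_node(template: CompiledTemplate, node: Node, index: int,
                  ctx: WorkerContext) -> str:
    ctx.current_index = index
    ctx._seq = 0
    ctx.visited += 1
    # aggregators observe every visited node, independent of rule outcome
    ctx.current_scope = "aggregator"
    for agg in template.aggregators:
        if agg.filter(ctx, node):
            elem = map_node(agg.spec, ctx, node)
            if elem is not None:
                ctx.contributions[agg.spec.name].append((index, elem))
    rule = dispatch(template, node)
    if rule is None:
        return "proceed"
    return apply_rule(rule, node, ctx).code


# ---------------------------------------------------------------------------
# execution drivers


def execute(template: CompiledTemplate, *, dry_run: bool = False,
            allow_destructive: bool = False,
            action_error_policy: str = "abort") -> ExecutionResult:
    """Serial execution: full walk, depth dispatch, aggregation, sinks."""
    run = RunContext(template, dry_run=dry_run,
                     allow_destructive=allow_destructive,
                     action_error_policy=action_error_policy)
    nodes = _snapshot(run)
    ctx = WorkerContext(run, worker_id=0)
    error: str | None = None
    try:
        for index, node in enumerate(nodes):
            if _process_node(template, node, index, ctx) == "quit":
                break
    except ExecutionError as exc:
        error = str(exc)
    return _finalize(run, [ctx], len(nodes), error)


def execute_parallel(template: CompiledTemplate, workers: int, *,
                     dry_run: bool = False, allow_destructive: bool = False,
                     action_error_policy: str = "abort",
                     delay: Callable[[Node], None] | None = None
                     ) -> ExecutionResult:
    """Parallel execution with worker-private state (lock-free contract).

    ``delay`` is a test seam: called once per node inside the owning
    worker to perturb scheduling; it must not touch shared state.
    """
    if workers < 1:
        raise ExecutionError(f"workers must be >= 1, got {workers}")
    run = RunContext(template, dry_run=dry_run,
                     allow_destructive=allow_destructive,
                     action_error_policy=action_error_policy)
    nodes = _snapshot(run)
    work: queue.SimpleQueue = queue.SimpleQueue()
    for item in enumerate(nodes):
        work.put(item)
    contexts = [WorkerContext(run, worker_id=i) for i in range(workers)]
    errors: list[str] = [None] * workers  # type: ignore[list-item]

    def loop(ctx: WorkerContext) -> None:
        while not run.quit_event.is_set():
            try:
                index, node = work.get_nowait()
            except queue.Empty:
                return
            if delay is not None:
                delay(node)
            try:
                if _process_node(template, node, index, ctx) == "quit":
                    run.quit_event.set()
            except ExecutionError as exc:
                errors[ctx.worker_id] = str(exc)
                run.quit_event.set()
                return

    threads = [threading.Thread(target=loop, args=(c,), daemon=True)
               for c in contexts]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    error = next((e for e in errors if e), None)
    return _finalize(run, contexts, len(nodes), error)


def _snapshot(run: RunContext) -> list[Node]:
    """Materialize the walk before any action can mutate the tree, so
    actions never feed the traversal within the same run."""
    skip = frozenset({run.quarantine_dir})
    return list(walk(run.input_root, run.config.traversal_order, skip))


def _finalize(run: RunContext, contexts: list[WorkerContext],
              node_count: int, error: str | None) -> ExecutionResult:
    template = run.template
    quits = sorted(q for ctx in contexts for q in ctx.quit_signals)
    quit_index: int | None = None
    quit_kind = None
    if quits:
        quit_index, quit_kind = quits[0]

    def in_scope(index: int) -> bool:
        return quit_index is None or index <= quit_index

    journal = [e for ctx in contexts for e in ctx.journal_entries
               if in_scope(e.walk_index)]
    failure_count = sum(
        1 for ctx in contexts for i in ctx.failures if in_scope(i))
    visited = node_count if quit_index is None else quit_index + 1

    finalize_seq = 0

    def run_effect(kind: str, path: str, detail: str) -> None:
        nonlocal finalize_seq
        journal.append(ActionEffect(
            walk_index=_FINALIZE_INDEX, seq=finalize_seq, path=path,
            rule_scope="run", kind=kind, detail=detail))
        finalize_seq += 1

    aggregates: dict[str, object] = {}
    sink_paths: dict[str, Path | None] = {}
    if error is None:
        try:
            for agg in template.aggregators:
                value = _finalize_aggregator(agg, contexts, in_scope,
                                             run_effect)
                aggregates[agg.spec.name] = value
                if value is not None and agg.spec.sink.kind != "stdout":
                    if run.dry_run:
                        run_effect("sink_write", str(agg.spec.sink.destination),
                                   f"{agg.spec.name} (dry-run)")
                        sink_paths[agg.spec.name] = None
                    else:
                        sink_paths[agg.spec.name] = write_sink(
                            value, agg.spec.sink, run.base_dir)
                        run_effect("sink_write", str(agg.spec.sink.destination),
                                   agg.spec.name)
                else:
                    sink_paths[agg.spec.name] = None
            _write_logs(run, contexts, in_scope, run_effect)
        except ExecutionError as exc:
            error = str(exc)

    journal.sort(key=lambda e: e.sort_key())
    if error is not None:
        status = "error"
    elif quit_kind == "quit_on_fail":
        status = "aborted"
    elif failure_count > 0:
        status = "validation_failures"
    else:
        status = "ok"
    return ExecutionResult(status=status, visited_count=visited,
                           fired=tuple(journal), aggregates=aggregates,
                           failure_count=failure_count,
                           sink_paths=sink_paths, quit_index=quit_index,
                           error=error)


_EMPTY_OK = {"count", "sum_size", "list_paths", "concat_tables"}


def _finalize_aggregator(agg: CompiledAggregator,
                         contexts: list[WorkerContext],
                         in_scope, run_effect) -> object:
    reducer = agg.reducer
    shards = []
    total = 0
    for ctx in contexts:
        acc = reducer.neutral()
        n = 0
        for index, elem in ctx.contributions[agg.spec.name]:
            if in_scope(index):
                acc = reducer.add(acc, elem)
                n += 1
        shards.append(Shard(owner=ctx.worker_id, partial=acc,
                            element_count=n))
        total += n
    merged = merge_shards(shards, reducer)
    if total == 0 and reducer.name not in _EMPTY_OK:
        run_effect("warn", agg.spec.name,
                   f"aggregator received no contributions")
        return None
    notes: list[str] = []
    value = reducer.finalize(merged, agg.spec, notes)
    for note in notes:
        run_effect("warn", agg.spec.name, note)
    return value


def _write_logs(run: RunContext, contexts: list[WorkerContext],
                in_scope, run_effect) -> None:
    merged: dict[str, list[tuple[int, str]]] = {}
    for ctx in contexts:
        for dest, lines in ctx.log_lines.items():
            merged.setdefault(dest, []).extend(
                (i, line) for i, line in lines if in_scope(i))
    for dest in sorted(merged):
        lines = [line for _, line in sorted(merged[dest])]
        if run.dry_run:
            run_effect("log_write", dest, "(dry-run)")
            continue
        path = Path(dest)
        if not path.is_absolute():
            path = run.base_dir / path
        atomic_write_text(path, "".join(f"{line}\n" for line in lines))
        run_effect("log_write", dest, f"{len(lines)} line(s)")
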