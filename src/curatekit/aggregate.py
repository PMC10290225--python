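"""Filter-map-reduce aggregation.

Each named aggregator filters visited nodes with a condition, maps the
matching ones to a contribution (path, size, loaded image, loaded
table), accumulates contributions in worker-local shards, and merges
the shards once at the end of the run.  Reducers declare a neutral
element and a commutative, associative merge, so the finalized result
does not depend on how nodes were scheduled across workers.
Order-sensitive outputs (path lists, concatenated tables, image stacks)
are canonicalized by an explicit sort key at finalization.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ExecutionError
from .io_utils import (atomic_write_bytes, load_image, load_table,
                       natural_key, save_image)
from .symbols import SymbolExpr

SINK_KINDS = ("text_list", "csv_table", "image_file", "stdout")


@dataclass(frozen=True)
class SinkSpec:
    kind: str = "stdout"
    destination: str | None = None


@dataclass(frozen=True)
class AggregatorSpec:
    """Declaration of one named filter-map-reduce pipeline."""

    name: str
    filter: SymbolExpr
    mapper: str
    reducer: str
    sink: SinkSpec = SinkSpec()
    sort_key: str | None = None         # regex with one capture group
    threshold_a: float = 0.0            # colocalization thresholds
    threshold_b: float = 0.0


@dataclass
class Shard:
    """A worker-private partial aggregate; merged exactly once."""

    owner: int
    partial: object
    element_count: int = 0
    consumed: bool = False


# ---------------------------------------------------------------------------
# image operations (the reducers' computational core)


def stack_images(slices: list[tuple[str, np.ndarray]]) -> np.ndarray:
    """Stack equally-shaped images along a new leading axis.

    Slice order is the natural sort of the sort keys ("z2" < "z10"),
    so a stack of 2D slices becomes a 3D volume and a stack of 3D
    volumes over time keys becomes a 4D hyperstack.
    """
    if not slices:
        raise ExecutionError("cannot stack zero slices")
    ordered = sorted(slices, key=lambda kv: natural_key(kv[0]))
    first_key, first = ordered[0]
    first = np.asarray(first)
    arrays = [first]
    for key, arr in ordered[1:]:
        arr = np.asarray(arr)
        if arr.shape != first.shape:
            raise ExecutionError(
                f"inconsistent slice shape: {key!r} has {arr.shape}, "
                f"{first_key!r} has {first.shape}")
        arrays.append(arr)
    return np.stack(arrays, axis=0)


def max_project(volume) -> np.ndarray:
    """Maximum intensity projection: elementwise max along the leading axis."""
    if isinstance(volume, list):
        volume = stack_images(volume)
    volume = np.asarray(volume)
    if volume.ndim < 2:
        raise ExecutionError("max projection needs at least a 2D stack")
    return volume.max(axis=0)


def describe_images(volume: np.ndarray) -> pd.DataFrame:
    """Per-slice intensity statistics and object metrics.

    Objects are connected components of the nonzero mask using
    8-connectivity within each 2D slice.  Standard deviation is the
    population (ddof=0) value so it is defined for single-pixel slices.
    """
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[None, ...]
    if volume.ndim != 3 or volume.size == 0:
        raise ExecutionError("describe_images expects a non-empty 2D/3D image")
    structure = np.ones((3, 3), dtype=bool)
    rows = []
    for z in range(volume.shape[0]):
        sl = volume[z].astype(np.float64)
        mask = sl != 0
        labels, count = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())[1:] if count else np.array([], int)
        q25, q50, q75 = np.percentile(sl, [25, 50, 75])
        rows.append({
            "slice": z,
            "mean": sl.mean(),
            "std": sl.std(ddof=0),
            "min": sl.min(),
            "max": sl.max(),
            "q25": q25,
            "median": q50,
            "q75": q75,
            "nonzero_fraction": mask.mean(),
            "object_count": int(count),
            "object_sizes": ";".join(str(int(s)) for s in sorted(sizes)),
        })
    return pd.DataFrame(rows)


def coloc(image_a: np.ndarray, image_b: np.ndarray, *,
          threshold_a: float = 0.0, threshold_b: float = 0.0,
          notes: list[str] | None = None) -> dict[str, float]:
    """Pixelwise colocalization metrics between two equally-shaped images.

    Returns Pearson r, Spearman rho (midranks for ties), Manders
    coefficients M1 = Σaᵢ·1[bᵢ>τ_b]/Σaᵢ and M2 (symmetric), and the
    fraction of pixels jointly above both thresholds.  Correlations are
    undefined (NaN) when either image is constant; a note is appended
    to ``notes`` in that case.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ExecutionError(
            f"colocalization needs identical shapes, got {a.shape} vs {b.shape}")
    av, bv = a.ravel(), b.ravel()
    ac, bc = av - av.mean(), bv - bv.mean()
    den = np.sqrt((ac * ac).sum() * (bc * bc).sum())
    if den == 0.0:
        r = float("nan")
        rho = float("nan")
        if notes is not None:
            notes.append("correlation undefined: constant image")
    else:
        r = float((ac * bc).sum() / den)
        rho = float(stats.spearmanr(av, bv).statistic)
    sum_a, sum_b = av.sum(), bv.sum()
    m1 = float((av * (bv > threshold_b)).sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float((bv * (av > threshold_a)).sum() / sum_b) if sum_b > 0 else float("nan")
    overlap = float(((av > threshold_a) & (bv > threshold_b)).mean())
    return {"pearson_r": r, "spearman_rho": rho,
            "manders_m1": m1, "manders_m2": m2, "overlap": overlap}


# ---------------------------------------------------------------------------
# mappers


def _map_path(ctx, node):
    return ctx.relpath(node)


def _map_name(ctx, node):
    return node.path.name


def _map_size(ctx, node):
    if node.kind != "file":
        return 0
    try:
        return node.path.stat().st_size
    except OSError:
        return None


def _map_image(ctx, node, spec: AggregatorSpec):
    try:
        arr = load_image(node.path)
    except Exception:
        return None
    key = node.path.name
    if spec.sort_key:
        m = re.search(spec.sort_key, node.path.name)
        if m:
            key = m.group(1) if m.groups() else m.group(0)
    return (key, arr)


def _map_table(ctx, node):
    try:
        return (ctx.relpath(node), load_table(node.path))
    except Exception:
        return None


#: mapper name → (needs_spec, element type)
MAPPERS: dict[str, tuple[Callable, str]] = {
    "path": (_map_path, "path"),
    "name": (_map_name, "path"),
    "size": (_map_size, "size"),
    "image": (_map_image, "image"),
    "table": (_map_table, "table"),
}


def map_node(spec: AggregatorSpec, ctx, node):
    """Apply an aggregator's mapper; None means 'no contribution'."""
    func, _ = MAPPERS[spec.mapper]
    if spec.mapper == "image":
        return func(ctx, node, spec)
    return func(ctx, node)


# ---------------------------------------------------------------------------
# reducers


class Reducer:
    """Accumulator contract: neutral / add / merge / finalize.

    ``merge`` must be commutative and associative; ``finalize`` may
    canonicalize order (sorting) so the output is schedule-independent.
    """

    name: str = ""
    elem_types: frozenset | None = None  # None = any element type

    def neutral(self):
        raise NotImplementedError

    def add(self, acc, elem):
        raise NotImplementedError

    def merge(self, a, b):
        raise NotImplementedError

    def finalize(self, acc, spec: AggregatorSpec,
                 notes: list[str] | None = None):
        raise NotImplementedError

    def accepts(self, elem_type: str) -> bool:
        return self.elem_types is None or elem_type in self.elem_types


class _Count(Reducer):
    name = "count"

    def neutral(self):
        return 0

    def add(self, acc, elem):
        return acc + 1

    def merge(self, a, b):
        return a + b

    def finalize(self, acc, spec, notes=None):
        return acc


class _SumSize(Reducer):
    name = "sum_size"
    elem_types = frozenset({"size"})

    def neutral(self):
        return 0

    def add(self, acc, elem):
        return acc + int(elem)

    def merge(self, a, b):
        return a + b

    def finalize(self, acc, spec, notes=None):
        return acc


class _ListAppend(Reducer):
    """Shared accumulator shape: a list merged by concatenation."""

    def neutral(self):
        return []

    def add(self, acc, elem):
        acc.append(elem)
        return acc

    def merge(self, a, b):
        return a + b


class _ListPaths(_ListAppend):
    name = "list_paths"
    elem_types = frozenset({"path"})

    def finalize(self, acc, spec, notes=None):
        return sorted(acc)


class _ConcatTables(_ListAppend):
    name = "concat_tables"
    elem_types = frozenset({"table"})

    def finalize(self, acc, spec, notes=None):
        if not acc:
            return pd.DataFrame()
        ordered = sorted(acc, key=lambda kv: natural_key(kv[0]))
        first_path, first = ordered[0]
        header = list(first.columns)
        frames = []
        for path, df in ordered:
            if list(df.columns) != header:
                raise ExecutionError(
                    f"incompatible CSV headers: {path!r} has "
                    f"{list(df.columns)}, {first_path!r} has {header}")
            df = df.copy()
            df["source_path"] = path
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


class _StackImages(_ListAppend):
    name = "stack_images"
    elem_types = frozenset({"image"})

    def finalize(self, acc, spec, notes=None):
        return stack_images(acc)


class _MaxProject(_ListAppend):
    name = "max_project"
    elem_types = frozenset({"image"})

    def finalize(self, acc, spec, notes=None):
        return max_project(stack_images(acc))


class _DescribeImages(_ListAppend):
    name = "describe_images"
    elem_types = frozenset({"image"})

    def finalize(self, acc, spec, notes=None):
        return describe_images(stack_images(acc))


class _Coloc(_ListAppend):
    name = "coloc"
    elem_types = frozenset({"image"})

    def finalize(self, acc, spec, notes=None):
        ordered = sorted(acc, key=lambda kv: natural_key(kv[0]))
        if len(ordered) < 2:
            raise ExecutionError(
                f"colocalization needs at least two images, got {len(ordered)}")
        if len(ordered) % 2:
            raise ExecutionError(
                f"colocalization pairs images; got an odd count {len(ordered)}")
        rows = []
        for i in range(0, len(ordered), 2):
            (ka, a), (kb, b) = ordered[i], ordered[i + 1]
            metrics = coloc(a, b, threshold_a=spec.threshold_a,
                            threshold_b=spec.threshold_b, notes=notes)
            rows.append({"image_a": ka, "image_b": kb, **metrics})
        return pd.DataFrame(rows)


REDUCERS: dict[str, Reducer] = {r.name: r for r in (
    _Count(), _SumSize(), _ListPaths(), _ConcatTables(), _StackImages(),
    _MaxProject(), _DescribeImages(), _Coloc())}


def reducers_builtin() -> set[str]:
    return set(REDUCERS)


def merge_shards(shards: list[Shard], reducer: Reducer):
    """Fold worker shards into one accumulator (order-independent)."""
    acc = reducer.neutral()
    for shard in shards:
        if shard.consumed:
            raise ExecutionError(
                f"shard owned by worker {shard.owner} merged twice")
        shard.consumed = True
        acc = reducer.merge(acc, shard.partial)
    return acc


# ---------------------------------------------------------------------------
# sinks


def render_aggregate(value) -> bytes:
    """Canonical byte serialization (used for sinks and identity tests)."""
    if isinstance(value, pd.DataFrame):
        buf = io.StringIO()
        value.to_csv(buf, index=False)
        return buf.getvalue().encode("utf-8")
    if isinstance(value, np.ndarray):
        out = io.BytesIO()
        np.save(out, value, allow_pickle=False)
        return out.getvalue()
    if isinstance(value, list):
        return ("".join(f"{line}\n" for line in value)).encode("utf-8")
    return (f"{value}\n").encode("utf-8")


def write_sink(value, sink: SinkSpec, base_dir: Path) -> Path | None:
    """Write a finalized aggregate; file writes are atomic."""
    if sink.kind == "stdout":
        return None
    if sink.destination is None:
        raise ExecutionError(f"sink kind {sink.kind!r} needs a destination")
    dest = Path(sink.destination)
    if not dest.is_absolute():
        dest = Path(base_dir) / dest
    try:
        if sink.kind == "text_list":
            if not isinstance(value, list):
                raise ExecutionError(
                    f"text_list sink needs a path list, got {type(value).__name__}")
            atomic_write_bytes(dest, render_aggregate(sorted(value)))
        elif sink.kind == "csv_table":
            if not isinstance(value, pd.DataFrame):
                raise ExecutionError(
                    f"csv_table sink needs a table, got {type(value).__name__}")
            atomic_write_bytes(dest, render_aggregate(value))
        elif sink.kind == "image_file":
            if not isinstance(value, np.ndarray):
                raise ExecutionError(
                    f"image_file sink needs an image, got {type(value).__name__}")
            dest.parent.mkdir(parents=True, exist_ok=True)
            tmp = dest.with_name(".tmp_ck_" + dest.name)
            save_image(tmp, value)
            os.replace(tmp, dest)
        else:
            raise ExecutionError(f"unknown sink kind {sink.kind!r}")
    except OSError as exc:
        raise ExecutionError(f"sink {dest} unwritable: {exc}") from exc
    return dest
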