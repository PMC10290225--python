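"""Seeded synthetic filesystem trees with ground-truth manifests.

Real curation targets (microscopy exports, tabular logs, opaque blobs)
are emulated by deterministic generators so every engine feature is
testable without external data.  The manifest enumerates exactly what
was written — paths, kinds, sizes, image shapes and content
descriptors, CSV headers — and doubles as the oracle for tests.

"Messy" naming plants one violation from each built-in condition
family (whitespace, hidden file, wrong/uppercase extension, non-ASCII
name, image dimensionality, CSV schema), each recorded in the manifest.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_utils import save_image

CSV_HEADER = ("x", "y", "z")


@dataclass(frozen=True)
class TreeSpec:
    depth: int = 3
    branching: tuple[int, int] = (1, 2)
    files_per_dir: tuple[int, int] = (2, 3)
    type_mix: tuple[tuple[str, float], ...] = (
        ("opaque", 0.35), ("png2d", 0.20), ("tiff3d", 0.20), ("csv", 0.25))
    naming: str = "clean"  # "clean" | "messy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for lo, hi in (self.branching, self.files_per_dir):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be nonnegative and ordered")
        total = sum(w for _, w in self.type_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("type mix weights must sum to 1")


@dataclass(frozen=True)
class ManifestEntry:
    relpath: str
    kind: str              # "file" | "directory"
    depth: int
    size: int
    meta: dict = field(default_factory=dict, compare=False)
    violation: str | None = None


@dataclass
class Manifest:
    seed: int
    spec: TreeSpec | None
    entries: list[ManifestEntry] = field(default_factory=list)

    # -- oracle helpers -----------------------------------------------------

    def files(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.kind == "file"]

    def file_count(self) -> int:
        return len(self.files())

    def total_bytes(self) -> int:
        return sum(e.size for e in self.files())

    def node_count(self) -> int:
        return len(self.entries)

    def violations(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.violation]

    def paths(self) -> set[str]:
        return {e.relpath for e in self.entries}

    def by_path(self) -> dict[str, ManifestEntry]:
        return {e.relpath: e for e in self.entries}


# ---------------------------------------------------------------------------
# images


def generate_image(path: Path, shape: tuple[int, ...], pattern: str,
                   seed: int = 0, value: int = 7,
                   n_blobs: int = 3) -> dict:
    """Write a grayscale image with known content; return its descriptor.

    Patterns: ``constant`` (every pixel = ``value``), ``blobs``
    (``n_blobs`` non-touching rectangles on zero background, positions
    and sizes recorded — the oracle for object metrics), ``ramp``
    (strictly increasing values — the oracle for correlation signs).
    """
    if len(shape) not in (2, 3) or any(d < 1 for d in shape):
        raise ValueError(f"shape must be 2D or 3D positive, got {shape}")
    rng = random.Random(seed)
    descriptor: dict = {"pattern": pattern, "shape": tuple(shape)}
    if pattern == "constant":
        arr = np.full(shape, value, dtype=np.uint8)
        descriptor["value"] = value
    elif pattern == "ramp":
        size = int(np.prod(shape))
        dtype = np.uint16 if size <= 65535 else np.float32
        arr = np.arange(1, size + 1, dtype=dtype).reshape(shape)
        descriptor["dtype"] = np.dtype(dtype).name
    elif pattern == "blobs":
        if len(shape) == 2:
            arr, boxes = _blob_slice(shape, n_blobs, rng)
            descriptor["boxes"] = boxes
        else:
            slices, all_boxes = [], []
            for _ in range(shape[0]):
                sl, boxes = _blob_slice(shape[1:], n_blobs, rng)
                slices.append(sl)
                all_boxes.append(boxes)
            arr = np.stack(slices, axis=0)
            descriptor["slices"] = all_boxes
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_image(path, arr)
    descriptor["dtype"] = np.dtype(arr.dtype).name
    return descriptor


def _blob_slice(shape: tuple[int, int], n: int,
                rng: random.Random) -> tuple[np.ndarray, list]:
    """Place ``n`` rectangles with >=1 pixel gap (so 8-connected
    components equal placed blobs exactly)."""
    arr = np.zeros(shape, dtype=np.uint8)
    occupied = np.zeros(shape, dtype=bool)  # blobs inflated by the gap
    boxes = []
    for _ in range(n):
        placed = False
        for _attempt in range(500):
            h = rng.randint(1, min(3, shape[0]))
            w = rng.randint(1, min(3, shape[1]))
            top = rng.randint(0, shape[0] - h)
            left = rng.randint(0, shape[1] - w)
            t0, l0 = max(0, top - 1), max(0, left - 1)
            if occupied[t0:top + h + 1, l0:left + w + 1].any():
                continue
            val = rng.randint(50, 255)
            arr[top:top + h, left:left + w] = val
            occupied[t0:top + h + 1, l0:left + w + 1] = True
            boxes.append({"top": top, "left": left, "height": h,
                          "width": w, "value": val})
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place {n} non-touching blobs in shape {shape}")
    return arr, boxes


# ---------------------------------------------------------------------------
# trees


class _TreeBuilder:
    def __init__(self, spec: TreeSpec, root: Path) -> None:
        self.spec = spec
        self.root = Path(root)
        self.rng = random.Random(spec.seed)
        self.manifest = Manifest(seed=spec.seed, spec=spec)
        self.file_counter = 0
        self.dir_counter = 0

    def build(self) -> Manifest:
        self.root.mkdir(parents=True, exist_ok=True)
        self._fill(self.root, 1)
        if self.spec.naming == "messy":
            self._plant_violations()
        self.manifest.entries.sort(key=lambda e: e.relpath)
        return self.manifest

    def _fill(self, directory: Path, depth: int) -> None:
        nfiles = self.rng.randint(*self.spec.files_per_dir)
        for _ in range(nfiles):
            self._make_file(directory, depth)
        if depth >= self.spec.depth:
            return
        ndirs = self.rng.randint(*self.spec.branching)
        for _ in range(ndirs):
            self.dir_counter += 1
            sub = directory / f"d{self.dir_counter:02d}"
            sub.mkdir()
            self._record(sub, depth, "directory")
            self._fill(sub, depth + 1)

    def _pick_type(self) -> str:
        roll = self.rng.random()
        acc = 0.0
        for name, weight in self.spec.type_mix:
            acc += weight
            if roll < acc:
                return name
        return self.spec.type_mix[-1][0]

    def _make_file(self, directory: Path, depth: int,
                   ftype: str | None = None, name: str | None = None,
                   violation: str | None = None, **image_kw) -> None:
        ftype = ftype or self._pick_type()
        self.file_counter += 1
        c = self.file_counter
        meta: dict = {"type": ftype}
        if ftype == "opaque":
            path = directory / (name or f"file{c:03d}.dat")
            payload = self.rng.randbytes(self.rng.randint(16, 256))
            path.write_bytes(payload)
        elif ftype == "csv":
            path = directory / (name or f"table{c:03d}.csv")
            header = image_kw.pop("header", CSV_HEADER)
            nrows = self.rng.randint(2, 5)
            rows = [",".join(str(self.rng.randint(0, 99))
                             for _ in header) for _ in range(nrows)]
            path.write_text(",".join(header) + "\n"
                            + "".join(r + "\n" for r in rows),
                            encoding="utf-8")
            meta.update(header=list(header), rows=nrows)
        elif ftype == "png2d":
            path = directory / (name or f"img{c:03d}.png")
            pattern = self.rng.choice(["constant", "blobs"])
            desc = generate_image(path, (8, 8), pattern,
                                  seed=self.rng.getrandbits(31),
                                  value=self.rng.randint(1, 255),
                                  n_blobs=self.rng.randint(1, 3))
            meta.update(desc)
        elif ftype == "tiff3d":
            path = directory / (name or f"vol{c:03d}.tif")
            shape = image_kw.pop("shape", (3, 6, 6))
            desc = generate_image(path, shape, "constant",
                                  value=self.rng.randint(1, 255))
            meta.update(desc)
        elif ftype == "tiff2d":
            path = directory / (name or f"flat{c:03d}.tif")
            desc = generate_image(path, (6, 6), "constant",
                                  value=self.rng.randint(1, 255))
            meta.update(desc)
        else:
            raise ValueError(f"unknown file type {ftype!r}")
        self._record(path, depth, "file", meta=meta, violation=violation)

    def _record(self, path: Path, depth: int, kind: str, meta: dict = None,
                violation: str | None = None) -> None:
        self.manifest.entries.append(ManifestEntry(
            relpath=path.relative_to(self.root).as_posix(), kind=kind,
            depth=depth, size=path.stat().st_size if kind == "file" else 0,
            meta=meta or {}, violation=violation))

    def _plant_violations(self) -> None:
        """One planted defect per built-in condition family, at seeded
        directories, all recorded in the manifest."""
        dirs = [self.root] + [self.root / e.relpath
                              for e in self.manifest.entries
                              if e.kind == "directory"]
        depth_of = {str(self.root): 1}
        for e in self.manifest.entries:
            if e.kind == "directory":
                depth_of[str(self.root / e.relpath)] = e.depth + 1
        plants = [
            ("csv", "my data 01.csv", "whitespace", {}),
            (".secret.dat", None, None, None),  # handled below
            ("png2d", "IMG_UPPER.PNG", "extension", {}),
            ("csv", "backup.csv.tmp", "extension", {}),
            ("opaque", "café.dat", "unicode", {}),
            ("tiff2d", "flat_volume.tif", "dimensionality", {}),
            ("csv", "table_bad.csv", "csv_schema", {"header": ("x", "z")}),
        ]
        for plant in plants:
            d = self.rng.choice(dirs)
            depth = depth_of[str(d)]
            if plant[0] == ".secret.dat":
                self._make_file(d, depth, ftype="opaque",
                                name=".secret.dat", violation="hidden")
            else:
                ftype, name, family, kw = plant
                self._make_file(d, depth, ftype=ftype, name=name,
                                violation=family, **kw)


def generate_tree(spec: TreeSpec, root: Path) -> Manifest:
    """Deterministically generate a tree; refuses a non-empty root."""
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"refusing to generate into non-empty {root}")
    return _TreeBuilder(spec, root).build()


def generate_gallery_fixture(root: Path, seed: int = 0,
                             naming: str = "clean") -> Manifest:
    """The standard fixture the example-recipe gallery runs against.

    A seeded random tree plus two deterministic planted directories:
    ``zstack/`` (z-numbered 2D slices exercising natural-sort
    stacking) and ``coloc/`` (an identical channel pair).
    """
    root = Path(root)
    spec = TreeSpec(seed=seed, naming=naming)
    manifest = generate_tree(spec, root)

    def record(path: Path, depth: int, kind: str, meta=None) -> None:
        manifest.entries.append(ManifestEntry(
            relpath=path.relative_to(root).as_posix(), kind=kind,
            depth=depth, size=path.stat().st_size if kind == "file" else 0,
            meta=meta or {}))

    zdir = root / "zstack"
    zdir.mkdir()
    record(zdir, 1, "directory")
    for z, value in ((1, 10), (2, 20), (10, 100)):
        path = zdir / f"z{z}.png"
        desc = generate_image(path, (8, 8), "constant", value=value)
        record(path, 2, "file", {"type": "png2d", **desc, "z": z})

    cdir = root / "coloc"
    cdir.mkdir()
    record(cdir, 1, "directory")
    desc = generate_image(cdir / "ch1.png", (8, 8), "blobs",
                          seed=seed + 1, n_blobs=3)
    record(cdir / "ch1.png", 2, "file", {"type": "png2d", **desc})
    import shutil

    shutil.copyfile(cdir / "ch1.png", cdir / "ch2.png")
    record(cdir / "ch2.png", 2, "file", {"type": "png2d", **desc})

    manifest.entries.sort(key=lambda e: e.relpath)
    return manifest
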