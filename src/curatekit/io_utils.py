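"""Shared I/O helpers: grayscale image and CSV loading, atomic writes,
content hashing of directory trees, natural sort keys."""

from __future__ import annotations

import hashlib
import os
import re
import tempfile
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd

IMAGE_EXTENSIONS = frozenset({".tif", ".tiff", ".png"})


def is_image_path(path: Path) -> bool:
    return path.suffix.lower() in IMAGE_EXTENSIONS


def load_image(path: Path) -> np.ndarray:
    """Load a grayscale 2D/3D image (TIFF or PNG) as a numpy array."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    if suffix == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)))
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse RGB(A)
            arr = arr[..., 0]
        return arr
    raise ValueError(f"unsupported image format: {path}")


def save_image(path: Path, array: np.ndarray) -> None:
    """Write a 2D/3D grayscale image; TIFF output is uncompressed."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        # grayscale planes, uncompressed: keeps byte output deterministic
        tifffile.imwrite(str(path), np.asarray(array),
                         photometric="minisblack")
        return
    if suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(str(path), np.asarray(array))
        return
    raise ValueError(f"unsupported image format: {path}")


def load_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def csv_header(path: Path) -> list[str]:
    return list(pd.read_csv(path, nrows=0).columns)


_NATURAL_RE = re.compile(r"(\d+)")


def natural_key(text: str) -> tuple:
    """Sort key where embedded integers compare numerically: z2 < z10.

    Numeric runs compare before letter runs of equal position, and the
    original string is appended as a deterministic tie-break.
    """
    parts = _NATURAL_RE.split(str(text))
    key = []
    for p in parts:
        if p.isdigit():
            key.append((0, int(p), ""))
        elif p:
            key.append((1, 0, p))
    return (tuple(key), str(text))


def atomic_write_bytes(path: Path, data: bytes) -> None:
    """Write via a temp file in the same directory + rename, so an
    interrupted write never leaves a partial file at the destination."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=".tmp_ck_")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def iter_tree(root: Path) -> Iterator[Path]:
    """Deterministic recursive enumeration (lexicographic byte order)."""
    root = Path(root)
    entries = sorted(root.iterdir(), key=lambda p: p.name.encode("utf-8"))
    for entry in entries:
        yield entry
        if entry.is_dir() and not entry.is_symlink():
            yield from iter_tree(entry)


def tree_hash(root: Path) -> str:
    """SHA-256 over (relative path, kind, content) of every entry.

    Identical trees hash identically on any platform; any content or
    layout change alters the digest.
    """
    root = Path(root)
    digest = hashlib.sha256()
    for entry in iter_tree(root):
        rel = entry.relative_to(root).as_posix()
        digest.update(rel.encode("utf-8"))
        if entry.is_dir():
            digest.update(b"/dir")
        else:
            digest.update(b"/file")
            digest.update(entry.read_bytes())
        digest.update(b"\x00")
    return digest.hexdigest()


def claim_destination(path: Path, max_tries: int = 10_000) -> Path:
    """Reserve a destination path, never overwriting an existing file.

    Tries ``name``, then ``name_1``, ``name_2``, ... before the
    extension.  The reservation uses O_CREAT|O_EXCL so concurrent
    workers arbitrate through the filesystem itself (no shared lock).
    Returns the claimed path (an empty placeholder file).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem, suffix = path.stem, path.suffix
    for i in range(max_tries):
        candidate = path if i == 0 else path.with_name(f"{stem}_{i}{suffix}")
        try:
            fd = os.open(candidate, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
        except FileExistsError:
            continue
        os.close(fd)
        return candidate
    raise OSError(f"could not claim a destination near {path}")
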