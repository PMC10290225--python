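"""Shared fixtures: seeded trees, gallery access, execution helpers."""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import pytest

from curatekit import (Manifest, TreeSpec, compile_template, execute,
                       execute_parallel, generate_gallery_fixture,
                       generate_tree, load_recipe)

REPO_ROOT = Path(__file__).resolve().parents[1]
RECIPES_DIR = REPO_ROOT / "recipes"


def gallery_recipes() -> list[Path]:
    paths = sorted(RECIPES_DIR.glob("*.toml"))
    assert paths, f"no recipes found under {RECIPES_DIR}"
    return paths


@pytest.fixture(scope="session")
def recipe_paths() -> list[Path]:
    return gallery_recipes()


def make_gallery_workdir(base: Path, seed: int = 1,
                         naming: str = "clean") -> tuple[Path, Manifest]:
    """A work directory holding the standard gallery fixture at data/."""
    base.mkdir(parents=True, exist_ok=True)
    manifest = generate_gallery_fixture(base / "data", seed=seed,
                                        naming=naming)
    return base, manifest


def run_recipe(recipe_path: Path, workdir: Path, *, workers: int = 0,
               dry_run: bool = False, delay=None,
               allow_destructive: bool = False):
    """Load a gallery recipe, rebase it onto ``workdir`` and execute."""
    doc = replace(load_recipe(recipe_path), base_dir=workdir)
    template = compile_template(doc)
    if workers:
        return execute_parallel(template, workers, dry_run=dry_run,
                                allow_destructive=allow_destructive,
                                delay=delay)
    return execute(template, dry_run=dry_run,
                   allow_destructive=allow_destructive)


@pytest.fixture()
def small_tree(tmp_path):
    """A small deterministic random tree plus its manifest."""
    manifest = generate_tree(TreeSpec(seed=7), tmp_path / "data")
    return tmp_path / "data", manifest


def walk_order_oracle(manifest: Manifest, order: str = "topdown") -> list[str]:
    """Independent prediction of the traversal sequence from the manifest.

    Top-down depth-first with byte-ordered siblings is exactly the
    lexicographic order of path-component tuples; bottom-up puts each
    directory after its subtree.
    """
    entries = {e.relpath: e for e in manifest.entries}
    paths = sorted(entries,
                   key=lambda p: [s.encode("utf-8") for s in p.split("/")])
    if order == "topdown":
        return paths

    def bottomup_key(p: str):
        parts = p.split("/")
        key = [(s.encode("utf-8"), 0) for s in parts]
        if entries[p].kind == "directory":
            name, _ = key[-1]
            key[-1] = (name, 1)  # a directory sorts after its subtree
        return key

    return sorted(paths, key=bottomup_key)
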