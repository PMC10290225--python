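"""Built-in conditions/actions, combinators and user extension."""

from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pytest

from curatekit import (RegistryError, Signature, SymbolExpr, TreeSpec,
                       builtin_actions, builtin_conditions, compile_template,
                       compose, default_registry, execute, generate_image,
                       generate_tree, parse_recipe, register_user_symbol,
                       tree_hash, walk)
from curatekit.compile import _compile_condition
from curatekit.engine import Node, RunContext, WorkerContext


def _template(tmp_path, extra: str = "", input_root: str = "data"):
    text = (f'[global]\ninput_root = "{input_root}"\n{extra}\n'
            '[[global.aggregators]]\nname = "n"\nfilter = "is_file"\n'
            'map = "path"\nreduce = "count"\n')
    return compile_template(parse_recipe(text, base_dir=tmp_path))


def _ctx(tmp_path, extra: str = "") -> WorkerContext:
    (tmp_path / "data").mkdir(exist_ok=True)
    run = RunContext(_template(tmp_path, extra), dry_run=False,
                     allow_destructive=False)
    return WorkerContext(run, worker_id=0)


def _eval(expr, ctx, node) -> bool:
    return _compile_condition(expr, default_registry())(ctx, node)


def _file_node(path: Path, depth: int = 1) -> Node:
    return Node(path, depth, "file")


class TestConditions:
    def test_extension_matching_is_case_insensitive(self, tmp_path):
        ctx = _ctx(tmp_path)
        node = _file_node(tmp_path / "cell_01.TIF")
        assert _eval(SymbolExpr("has_extension", (".tif",)), ctx, node)
        assert not _eval(SymbolExpr("has_extension", (".png",)), ctx, node)

    def test_image_dimensionality(self, tmp_path):
        ctx = _ctx(tmp_path)
        generate_image(tmp_path / "vol.tif", (5, 4, 4), "constant")
        generate_image(tmp_path / "flat.png", (4, 4), "constant")
        dims3 = SymbolExpr("image_has_dims", (3,))
        assert _eval(dims3, ctx, _file_node(tmp_path / "vol.tif"))
        assert not _eval(dims3, ctx, _file_node(tmp_path / "flat.png"))

    def test_csv_column_subset(self, tmp_path):
        ctx = _ctx(tmp_path)
        good = tmp_path / "good.csv"
        good.write_text("x,y,z\n1,2,3\n")
        bad = tmp_path / "bad.csv"
        bad.write_text("x,z\n1,3\n")
        cols = SymbolExpr("csv_has_columns", ("x", "y"))
        assert _eval(cols, ctx, _file_node(good))
        assert not _eval(cols, ctx, _file_node(bad))

    def test_name_matches_literal_vs_regex(self, tmp_path):
        node = _file_node(tmp_path / "img12.png")
        literal_ctx = _ctx(tmp_path)
        pattern = SymbolExpr("name_matches", (r"img\d+\.png",))
        assert not _eval(pattern, literal_ctx, node)
        regex_ctx = _ctx(tmp_path, extra="regex_enabled = true")
        assert _eval(pattern, regex_ctx, node)

    def test_vanished_path_is_false_and_journaled(self, tmp_path):
        ctx = _ctx(tmp_path)
        node = _file_node(tmp_path / "gone.txt")
        assert not _eval(SymbolExpr("size_at_least", (1,)), ctx, node)
        assert any(e.kind == "warn" for e in ctx.journal_entries)

    def test_size_conditions_ignore_directories(self, tmp_path):
        ctx = _ctx(tmp_path)
        node = Node(tmp_path, 1, "directory")
        assert not _eval(SymbolExpr("size_at_least", (0,)), ctx, node)


class TestComposites:
    def test_nested_truth_table_example(self, tmp_path):
        ctx = _ctx(tmp_path)
        expr = compose("all_of", [
            SymbolExpr("is_file"),
            compose("any_of", [SymbolExpr("has_extension", (".tif",)),
                               SymbolExpr("has_extension", (".png",))])])
        assert _eval(expr, ctx, _file_node(tmp_path / "x.png"))
        assert not _eval(expr, ctx, _file_node(tmp_path / "x.csv"))

    def test_not_arity(self):
        with pytest.raises(ValueError):
            compose("not", [SymbolExpr("is_file"), SymbolExpr("is_dir")])

    def test_random_composites_agree_with_truth_table_oracle(self, tmp_path):
        """Seeded random boolean composites vs an independent evaluator."""
        leaves = {
            "is_file": lambda n: n.kind == "file",
            "is_dir": lambda n: n.kind == "directory",
            "is_hidden": lambda n: n.path.name.startswith("."),
            "name_is_integer": lambda n: (
                n.path.stem if n.kind == "file" else n.path.name).isdigit(),
        }
        rng = random.Random(42)

        def random_expr(depth: int) -> SymbolExpr:
            if depth == 0 or rng.random() < 0.4:
                return SymbolExpr(rng.choice(list(leaves)),
                                  negated=rng.random() < 0.3)
            op = rng.choice(["all_of", "any_of", "not"])
            n = 1 if op == "not" else rng.randint(1, 3)
            return SymbolExpr(op, tuple(random_expr(depth - 1)
                                        for _ in range(n)))

        def oracle(expr: SymbolExpr, node) -> bool:
            if expr.name == "not":
                value = not oracle(expr.args[0], node)
            elif expr.name == "all_of":
                value = all(oracle(a, node) for a in expr.args)
            elif expr.name == "any_of":
                value = any(oracle(a, node) for a in expr.args)
            else:
                value = leaves[expr.name](node)
            return (not value) if expr.negated else value

        manifest = generate_tree(TreeSpec(seed=11), tmp_path / "data")
        ctx = _ctx(tmp_path)
        nodes = list(walk(tmp_path / "data"))
        registry = default_registry()
        for _ in range(200):
            expr = random_expr(3)
            compiled = _compile_condition(expr, registry)
            node = rng.choice(nodes)
            assert compiled(ctx, node) == oracle(expr, node)


class TestActions:
    def test_rename_transform_composition(self, tmp_path):
        src = tmp_path / "data" / "My Data.TIF"
        src.parent.mkdir()
        src.write_bytes(b"x")
        text = ('[global]\ninput_root = "data"\nregex_enabled = true\n'
                '[template.any]\n'
                "conditions = [[\"name_matches\", '.*\\s.*']]\n"
                'actions = [["rename", "whitespace_to_underscore", '
                '"to_lowercase"]]\n')
        result = execute(compile_template(parse_recipe(text,
                                                       base_dir=tmp_path)))
        assert (tmp_path / "data" / "my_data.tif").exists()
        assert not src.exists()
        assert any(e.kind == "rename" for e in result.fired)

    def test_quarantine_preserves_relative_path(self, tmp_path):
        data = tmp_path / "data"
        (data / "a").mkdir(parents=True)
        (data / "a" / "junk.tmp").write_bytes(b"junk")
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = [["has_extension", ".tmp"]]\n'
                'actions = ["remove"]\ncounteractions = ["warn"]\n')
        execute(compile_template(parse_recipe(text, base_dir=tmp_path)))
        assert not (data / "a" / "junk.tmp").exists()
        assert (tmp_path / "data_quarantine" / "a" / "junk.tmp").exists()

    def test_flatten_produces_distinct_path_derived_names(self, tmp_path):
        data = tmp_path / "data"
        for sub in ("a/b", "a/d"):
            (data / sub).mkdir(parents=True)
            (data / sub / "c.tif").write_bytes(sub.encode())
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = [["has_extension", ".tif"]]\n'
                'actions = [["flatten_to", "out"]]\n'
                'counteractions = ["warn"]\n')
        result = execute(compile_template(parse_recipe(text,
                                                       base_dir=tmp_path)))
        flat = sorted(p.name for p in (tmp_path / "out").iterdir())
        assert flat == ["a_b_c.tif", "a_d_c.tif"]
        assert sum(e.kind == "copy" for e in result.fired) == 2

    def test_copy_collision_gets_numeric_suffix(self, tmp_path):
        data = tmp_path / "data"
        for sub in ("a", "b"):
            (data / sub).mkdir(parents=True)
            (data / sub / "same.csv").write_text("x\n1\n")
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = ["is_csv"]\n'
                'actions = [["copy_to", "out"]]\ncounteractions = ["warn"]\n')
        execute(compile_template(parse_recipe(text, base_dir=tmp_path)))
        names = sorted(p.name for p in (tmp_path / "out").iterdir())
        assert names == ["same.csv", "same_1.csv"]

    def test_condition_only_recipe_leaves_tree_unchanged(self, tmp_path):
        generate_tree(TreeSpec(seed=3), tmp_path / "data")
        before = tree_hash(tmp_path / "data")
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = ["is_file", "not is_hidden"]\n'
                'actions = [["log_to_file", "out/log.txt"]]\n'
                'counteractions = ["warn"]\n')
        execute(compile_template(parse_recipe(text, base_dir=tmp_path)))
        assert tree_hash(tmp_path / "data") == before


class TestUserSymbols:
    def test_registration_round_trip(self, tmp_path):
        registry = default_registry()
        register_user_symbol(registry, "condition", "is_weekend_file",
                             lambda ctx, node: node.path.stem.endswith("sat"),
                             Signature())
        (tmp_path / "data").mkdir()
        (tmp_path / "data" / "log_sat.txt").write_text("x")
        (tmp_path / "data" / "log_mon.txt").write_text("x")
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = ["is_weekend_file"]\n')
        doc = parse_recipe(text, base_dir=tmp_path)
        result = execute(compile_template(doc, registry))
        assert result.failure_count == 1  # the weekday file

    def test_shadowing_builtin_forbidden(self):
        registry = default_registry()
        with pytest.raises(RegistryError, match="shadow"):
            register_user_symbol(registry, "condition", "is_file",
                                 lambda ctx, node: True)

    def test_raising_user_condition_contained(self, tmp_path):
        registry = default_registry()

        def fragile(ctx, node):
            if node.path.name == "boom.txt":
                raise RuntimeError("bad node")
            return True

        register_user_symbol(registry, "condition", "fragile", fragile)
        data = tmp_path / "data"
        data.mkdir()
        (data / "boom.txt").write_text("x")
        (data / "fine.txt").write_text("x")
        text = ('[global]\ninput_root = "data"\n[template.any]\n'
                'conditions = ["fragile"]\n')
        result = execute(compile_template(parse_recipe(text,
                                                       base_dir=tmp_path),
                                          registry))
        assert result.status == "validation_failures"
        assert result.failure_count == 1
        assert any(e.kind == "warn" and "raised" in e.detail
                   for e in result.fired)

    def test_builtin_inventories(self):
        assert {"is_file", "has_extension", "csv_has_columns", "always",
                "never"} <= builtin_conditions()
        assert {"copy_to", "move_to", "rename", "remove", "quit",
                "quit_on_fail"} <= builtin_actions()
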