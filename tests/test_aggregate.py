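"""Reducers, image operations, colocalization, shard merging, sinks."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curatekit import (ExecutionError, Shard, SinkSpec, coloc,
                       describe_images, max_project, merge_shards,
                       natural_key, reducers_builtin, stack_images,
                       write_sink)
from curatekit.aggregate import REDUCERS, AggregatorSpec, render_aggregate

SPEC = AggregatorSpec(name="t", filter=None, mapper="path", reducer="count")


class TestReducerAlgebra:
    def test_builtin_inventory(self):
        assert reducers_builtin() == {
            "count", "sum_size", "list_paths", "concat_tables",
            "stack_images", "max_project", "describe_images", "coloc"}

    @pytest.mark.parametrize("name", ["count", "sum_size", "list_paths"])
    def test_neutral_elements(self, name):
        reducer = REDUCERS[name]
        assert reducer.finalize(reducer.neutral(), SPEC) in (0, [])

    @given(st.lists(st.integers(0, 1000), max_size=40),
           st.integers(1, 5))
    @settings(deadline=None, max_examples=50)
    def test_sum_partition_invariance(self, sizes, nshards):
        """Any partition of elements into shards gives the single-shard
        result (commutative/associative merge)."""
        reducer = REDUCERS["sum_size"]
        single = reducer.neutral()
        for s in sizes:
            single = reducer.add(single, s)
        shards = []
        for i in range(nshards):
            acc = reducer.neutral()
            for s in sizes[i::nshards]:
                acc = reducer.add(acc, s)
            shards.append(Shard(owner=i, partial=acc))
        assert merge_shards(shards, reducer) == single

    def test_merge_order_invariance_exhaustive(self):
        reducer = REDUCERS["list_paths"]
        parts = [["b"], ["a", "c"], ["d"]]
        results = set()
        for perm in itertools.permutations(parts):
            shards = [Shard(owner=i, partial=list(p))
                      for i, p in enumerate(perm)]
            merged = merge_shards(shards, reducer)
            results.add(tuple(reducer.finalize(merged, SPEC)))
        assert results == {("a", "b", "c", "d")}

    def test_merge_empty_is_neutral(self):
        for name in ("count", "sum_size", "list_paths"):
            reducer = REDUCERS[name]
            assert merge_shards([], reducer) == reducer.neutral()

    def test_double_merge_rejected(self):
        reducer = REDUCERS["count"]
        shard = Shard(owner=0, partial=3)
        merge_shards([shard], reducer)
        with pytest.raises(ExecutionError, match="twice"):
            merge_shards([shard], reducer)

    def test_concat_tables_requires_identical_headers(self):
        reducer = REDUCERS["concat_tables"]
        acc = [("a.csv", pd.DataFrame({"x": [1]})),
               ("b.csv", pd.DataFrame({"y": [2]}))]
        with pytest.raises(ExecutionError) as exc:
            reducer.finalize(acc, SPEC)
        assert "a.csv" in str(exc.value) and "b.csv" in str(exc.value)

    def test_concat_tables_adds_provenance(self):
        reducer = REDUCERS["concat_tables"]
        acc = [("b.csv", pd.DataFrame({"x": [2]})),
               ("a.csv", pd.DataFrame({"x": [1]}))]
        out = reducer.finalize(acc, SPEC)
        assert list(out.columns) == ["x", "source_path"]
        assert list(out["source_path"]) == ["a.csv", "b.csv"]


class TestStacking:
    def test_natural_sort_beats_lexicographic(self):
        slices = [("z1.tif", np.full((2, 2), 1)),
                  ("z10.tif", np.full((2, 2), 10)),
                  ("z2.tif", np.full((2, 2), 2))]
        volume = stack_images(slices)
        assert volume.shape == (3, 2, 2)
        assert [int(volume[i, 0, 0]) for i in range(3)] == [1, 2, 10]

    def test_singleton_stack(self):
        arr = np.arange(6).reshape(2, 3)
        volume = stack_images([("only", arr)])
        assert volume.shape == (1, 2, 3)
        np.testing.assert_array_equal(volume[0], arr)

    def test_time_series_of_volumes_becomes_4d(self):
        rng = np.random.default_rng(0)
        blocks = {f"t{i}": rng.integers(0, 255, (3, 4, 5)).astype(np.uint8)
                  for i in range(4)}
        hyper = stack_images(list(blocks.items()))
        assert hyper.shape == (4, 3, 4, 5)
        for i in range(4):
            np.testing.assert_array_equal(hyper[i], blocks[f"t{i}"])

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ExecutionError, match="zero"):
            stack_images([])
        with pytest.raises(ExecutionError, match="z2"):
            stack_images([("z1", np.zeros((2, 2))),
                          ("z2", np.zeros((3, 2)))])

    def test_max_project_elementwise(self):
        volume = np.array([[[1, 5], [3, 2]], [[4, 0], [2, 9]]])
        np.testing.assert_array_equal(max_project(volume),
                                      [[4, 5], [3, 9]])

    def test_stack_then_project_equals_brute_force(self):
        rng = np.random.default_rng(7)
        slices = [(f"z{i}", rng.integers(0, 99, (6, 6)))
                  for i in range(8)]
        projected = max_project(stack_images(slices))
        brute = np.maximum.reduce([a for _, a in slices])
        np.testing.assert_array_equal(projected, brute)

    def test_natural_key_ordering(self):
        names = ["z10", "z2", "z1", "a2b10", "a2b9"]
        assert sorted(names, key=natural_key) == [
            "a2b9", "a2b10", "z1", "z2", "z10"]


class TestDescribe:
    def test_constant_slice(self):
        table = describe_images(np.full((1, 4, 4), 7.0))
        row = table.iloc[0]
        assert row["mean"] == 7 and row["std"] == 0
        assert row["min"] == row["max"] == 7
        assert row["object_count"] == 1  # one blob covering the slice

    def test_l_shaped_blob(self):
        sl = np.zeros((5, 5))
        sl[1, 1] = sl[2, 1] = sl[2, 2] = 1  # 3-pixel L
        row = describe_images(sl[None]).iloc[0]
        assert row["object_count"] == 1
        assert row["object_sizes"] == "3"
        assert row["nonzero_fraction"] == pytest.approx(3 / 25)

    def test_diagonal_touch_is_one_object(self):
        sl = np.zeros((3, 3))
        sl[0, 0] = sl[1, 1] = 1  # 8-connectivity joins diagonals
        assert describe_images(sl[None]).iloc[0]["object_count"] == 1

    def test_all_zero_slice_defined(self):
        row = describe_images(np.zeros((1, 3, 3))).iloc[0]
        assert row["object_count"] == 0
        assert row["object_sizes"] == ""
        assert row["std"] == 0


class TestColoc:
    def test_identity_is_perfect_correlation(self):
        rng = np.random.default_rng(1)
        a = rng.random((16, 16)) + 0.5
        m = coloc(a, a)
        assert m["pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert m["spearman_rho"] == pytest.approx(1.0, abs=1e-12)
        assert m["manders_m1"] == pytest.approx(1.0, abs=1e-12)
        assert m["manders_m2"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_inversion_is_anticorrelated(self):
        a = np.arange(64, dtype=float).reshape(8, 8)
        b = -a + a.max()
        assert coloc(a, b)["pearson_r"] == pytest.approx(-1.0, abs=1e-12)

    def test_disjoint_supports_zero_manders(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[:, :2] = 1.0
        b[:, 2:] = 1.0
        m = coloc(a, b)
        assert m["manders_m1"] == 0.0
        assert m["manders_m2"] == 0.0
        assert m["overlap"] == 0.0

    def test_pearson_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        expected = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert coloc(a, b)["pearson_r"] == pytest.approx(expected,
                                                         abs=1e-12)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        m_ab, m_ba = coloc(a, b), coloc(b, a)
        assert m_ab["pearson_r"] == pytest.approx(m_ba["pearson_r"])
        assert m_ab["spearman_rho"] == pytest.approx(m_ba["spearman_rho"])
        assert m_ab["manders_m1"] == pytest.approx(m_ba["manders_m2"])
        assert m_ab["manders_m2"] == pytest.approx(m_ba["manders_m1"])

    def test_constant_images_noted_as_undefined(self):
        notes: list[str] = []
        m = coloc(np.ones((3, 3)), np.ones((3, 3)), notes=notes)
        assert np.isnan(m["pearson_r"])
        assert notes  # journaled explanation
        assert m["manders_m1"] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ExecutionError, match="shape"):
            coloc(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSinks:
    def test_text_list_sorted_with_trailing_newline(self, tmp_path):
        sink = SinkSpec("text_list", "out/list.txt")
        write_sink(["b", "a", "c"], sink, tmp_path)
        assert (tmp_path / "out" / "list.txt").read_text() == "a\nb\nc\n"

    def test_csv_round_trip(self, tmp_path):
        table = describe_images(np.arange(32, dtype=float).reshape(2, 4, 4))
        sink = SinkSpec("csv_table", "stats.csv")
        write_sink(table, sink, tmp_path)
        back = pd.read_csv(tmp_path / "stats.csv")
        pd.testing.assert_frame_equal(
            back.drop(columns="object_sizes"),
            table.drop(columns="object_sizes"), check_dtype=False)

    def test_interrupted_write_leaves_no_partial_file(self, tmp_path,
                                                      monkeypatch):
        import os as _os

        real_replace = _os.replace

        def failing_replace(src, dst, *a, **k):
            raise OSError("injected fault")

        monkeypatch.setattr("os.replace", failing_replace)
        sink = SinkSpec("text_list", "fragile.txt")
        with pytest.raises(ExecutionError):
            write_sink(["x"], sink, tmp_path)
        monkeypatch.setattr("os.replace", real_replace)
        assert not (tmp_path / "fragile.txt").exists()

    def test_render_is_deterministic(self):
        table = pd.DataFrame({"a": [1.5, 2.5]})
        assert render_aggregate(table) == render_aggregate(table.copy())
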