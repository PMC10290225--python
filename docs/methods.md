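# Methods

This note documents the semantics of the recipe dialect, the execution
model, the numerical and design choices behind them, and what the
synthetic fixtures do and do not establish about real data.

## The recipe dialect

Recipes are TOML 1.0, UTF-8. Two top-level tables are recognized:
`[global]` and `[template]`. Unrecognized keys anywhere are hard
errors, not warnings: a recipe is a contract between data producers
and consumers, and a silently ignored typo (`pralellel`) would void it
while appearing to hold. Error messages carry a best-effort source
line; valid-TOML key positions are not retained by the parser, so the
line is found by scanning the source text for the offending token.

Symbols (conditions and actions) are written as a bare name
(`"is_file"`), a negated name (`"not is_file"`), or an array currying
literal arguments (`["has_extension", ".csv"]`). The combinators
`all_of`, `any_of`, `not` take symbol expressions as arguments and
nest without limit. Aliases declared in `[global.shared_definitions]`
are expanded by substitution at compile time, so the execution engine
never sees an alias; cycles are rejected during validation.

Every symbol carries a declared signature (arity and argument kinds),
checked during validation, so argument errors surface before any
filesystem access. Validation returns *all* problems, not the first,
each with a nearest-name suggestion where applicable. Compilation
refuses any document with outstanding diagnostics — there are no
partial templates.

Paths inside a recipe (input root, sink destinations, log files,
copy/move targets) resolve relative to the recipe file's directory
unless absolute.

## Traversal and dispatch

The input root itself is not a node; its immediate children are depth
1. Sibling order is the lexicographic order of name bytes — not
filesystem order — which is what makes "left to right" evaluation
reproducible across platforms. Top-down yields a directory before its
contents, bottom-up after; hidden entries are yielded (conditions
decide relevance).

A node at depth *k* is handled by the `level_k` rule if one exists,
else by the `any` rule, else by no rule (it still counts as visited
and is still observed by aggregators). Level-specific beats `any`
rather than both firing: single-rule-per-node semantics are
predictable, and conjunction of concerns is expressible inside one
rule with combinators.

`execute` materializes the complete walk before dispatching any rule,
for both serial and parallel runs. This is a deliberate strengthening
of per-directory snapshotting: actions that create or move entries can
never feed the traversal within the same run, and serial and parallel
modes are guaranteed to see the identical node set even under
mutation. The quarantine directory is excluded from the walk in case
it is placed inside the root.

Failure accounting: a node fails when its rule's predicate is false
*and* the author supplied no counteractions; authored counteractions
mean the failure was handled. `act_on_success = false` swaps the two
action sequences at compile time.

## Parallel execution and early exit

Worker threads each own a private journal, private per-aggregator
contribution lists and a private early-exit signal list; no shared
mutable state exists during a run, so data races are impossible by
construction rather than by locking discipline. Shards are merged
exactly once at completion; reducers declare a commutative,
associative merge with a neutral element, and order-sensitive outputs
(path lists, table concatenation, image stacks) canonicalize by an
explicit sort key at finalization, so finalized results are
schedule-independent.

Every journal entry and aggregator contribution is tagged with the
node's index in the serial walk order. When a `quit` or `quit_on_fail`
fires, finalization truncates journals, contributions, failure counts
and the visited count at the minimal quit index observed across
workers. In-flight nodes past that index may have been evaluated
speculatively, but their traces are dropped, so finalized aggregates
and canonical journals are identical to the serial run. The one
residual weakness: a *mutating* action on a speculatively processed
node past the quit index has already touched the filesystem and cannot
be untraced; combining early exit with mutation in parallel mode is
therefore best-effort, and the shipped early-exit recipes are
journal-only. Destination collisions between concurrent workers are
arbitrated through the filesystem itself (`O_CREAT|O_EXCL` claims),
not through an in-process lock.

## Actions and safety

* `remove` quarantines by default, moving the node under a run-scoped
  quarantine directory (`<root>_quarantine` beside the input root)
  while preserving its relative path, so a run is reversible by
  moving the quarantine contents back. True deletion requires
  `destructive_allowed = true` in the recipe *and* the
  `--allow-destructive` flag at invocation.
* Mutating actions never overwrite: collisions append `_1`, `_2`, …
  before the extension. `flatten_to` derives its destination name from
  the relative path (components joined by `_`), which is unique by
  construction and keeps parallel runs schedule-independent; the
  numeric suffix remains as a fallback.
* Extension matching is case-insensitive (extensions are conventions);
  `name_matches` is case-sensitive and is a full-name match — literal
  equality by default, a regex `fullmatch` when `regex_enabled` is
  set (name contracts are exact).
* `size_at_least` / `size_at_most` apply to files only and evaluate
  false on directories: a directory's `st_size` is
  filesystem-dependent and would break cross-platform determinism.
* A condition evaluated on a path that vanished mid-run evaluates
  false and journals a warning; the run continues. User-registered
  conditions are additionally exception-contained (any exception →
  false plus a journaled warning); user actions that raise journal an
  error and, under the default policy, abort the run — one bad node
  should not silently corrupt a large curation pass, but the operator
  decides between abort and continue.
* `log_to_file` lines are buffered per worker and written once at
  finalization in walk order, which keeps log files byte-identical
  across worker counts. All file outputs (logs, sinks) are written via
  temp-file-plus-rename, so an interrupted run leaves no partial file
  at a destination.

## Aggregation

Mappers: `path`, `name`, `size`, `image` (grayscale TIFF/PNG), `table`
(CSV via pandas). Reducers: `count`, `sum_size`, `list_paths`,
`concat_tables`, `stack_images`, `max_project`, `describe_images`,
`coloc`. Mapper output type and reducer element type are checked at
compile time.

Aggregators observe every visited node through their own filter,
independent of rule outcomes — a counting recipe needs no rule blocks
at all. Rules can additionally push nodes into a named aggregator with
`add_to_list` / `add_to_aggregator`; an aggregator meant to be fed
only by rules should use `filter = "never"`.

Choices worth spelling out:

* **Stack order** is the natural sort (embedded integers compare
  numerically, `z2 < z10`) of the file name, or of a regex capture
  group when `sort_key` is given. Stacking 2D slices yields a 3D
  volume; stacking 3D volumes over time keys yields 4D.
* **`describe_images`** reports per-slice mean, population standard
  deviation (ddof = 0, defined even for a single pixel), min, max,
  quartiles, nonzero fraction, and object count/sizes where objects
  are 8-connected components of the nonzero mask *within* each 2D
  slice (the metrics are explicitly slice-wise; no 3D 26-connectivity).
* **`coloc`** pairs images by natural-sorted key, consecutively
  (first with second, …); exactly two images give one record. Manders
  thresholds default to 0 with per-aggregator overrides; no automatic
  (Costes-style) threshold estimation — deterministic defaults keep
  the closed-form contracts exact. The `overlap` metric is the count
  of pixels jointly above both thresholds divided by the total pixel
  count. With a constant image the correlations are undefined and
  reported as NaN with a journaled note; Manders coefficients remain
  defined while their denominators are positive. Spearman ρ is
  computed with midranks for ties (scipy's implementation of exactly
  that definition); Pearson and Manders are computed directly from
  their closed forms in float64.
* **`concat_tables`** requires byte-identical headers and appends a
  `source_path` provenance column — silent schema drift is precisely
  the failure mode the tool exists to catch.
* An image/table reducer that received zero contributions finalizes to
  an empty value with a journaled warning instead of aborting the run;
  the direct `stack_images` operation still rejects empty input (a
  zero-slice volume has no meaning).

Sinks: sorted UTF-8 text lists, RFC-4180 CSV with header, uncompressed
grayscale TIFF, or a human-readable stdout summary. File sinks are
atomic. SQLite output is deliberately out of scope; the sink kind enum
is the seam where it would plug in. Likewise, readers beyond grayscale
TIFF/PNG images and CSV tables (HDF5, MAT, JSON, point clouds, meshes)
are out of scope; the user-symbol registry is the extension seam.

## Synthetic fixtures

The fixture generator emulates the shape of mixed bioimaging datasets:
nested directories holding opaque binary files, 8×8 grayscale PNGs
(constant or blob-patterned), small 3D TIFF volumes and 3-column CSV
tables, all from a single integer seed with byte-deterministic output
(uncompressed encoders, fixed sibling order). The default tree
(depth 3, 1–2 subdirectories and 2–3 files per directory) keeps a
single fixture around 20–30 nodes so the full gallery sweep and the
serial≡parallel matrix stay fast; the counting contract is separately
exercised on a ≥1000-node tree (depth 4, branching 4–5, 10–12 files
per directory). "Messy" naming plants exactly one violation per
built-in condition family — whitespace in a name, a hidden file, an
uppercase extension, a wrong double extension, a non-ASCII name, a 2D
TIFF where 3D is expected, a CSV missing a required column — each
recorded in the manifest, so a validation recipe's failure count has
an exact oracle. The gallery fixture adds two deterministic planted
directories: `zstack/` (z-numbered slices including the `z10`
natural-sort trap) and `coloc/` (an identical channel pair).

What passing these tests shows: the engine's traversal, dispatch,
aggregation, parallel merge and safety contracts hold exactly on trees
whose ground truth is known. What it does not show: behaviour on
exotic filesystems (case-insensitive name collisions, non-UTF-8
names), on images larger than memory, or on the long tail of
real-world TIFF variants — the fixtures use small, well-formed,
uncompressed files by construction.

## Known limitations

* Parallelism uses threads; conditions and actions dominated by pure
  Python (rather than I/O or numpy) will not scale past the
  interpreter lock. The lock-free shard design is about correctness
  and determinism, not about circumventing that.
* Early exit in parallel mode cannot retract filesystem mutations
  performed speculatively past the quit index (see above).
* `walk` follows the real directory tree; symbolic links are yielded
  as files and never followed as directories, so link cycles cannot
  trap the traversal, but link-heavy layouts are otherwise untested.
* Journal source lines for unknown keys are best-effort (first textual
  occurrence of the token).
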