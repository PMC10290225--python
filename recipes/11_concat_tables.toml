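# Row-concatenate all schema-conforming CSV tables, with provenance.
[global]
input_root = "data"

[[global.aggregators]]
name = "all_tables"
filter = ["all_of", "is_csv", ["csv_has_columns", "x", "y", "z"]]
map = "table"
reduce = "concat_tables"
sink = { kind = "csv_table", destination = "out/all_tables.csv" }
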