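# Every CSV table must carry the x, y, z columns.
[global]
input_root = "data"

[template.any]
conditions = [["any_of", "not is_csv", ["csv_has_columns", "x", "y", "z"]]]
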