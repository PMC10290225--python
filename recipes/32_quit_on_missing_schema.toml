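# Abort the run as soon as a CSV violates the schema.
[global]
input_root = "data"

[template.any]
conditions = [["any_of", "not is_csv", ["csv_has_columns", "x", "y", "z"]]]
counteractions = ["quit_on_fail"]
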