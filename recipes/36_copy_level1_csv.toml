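# Copy first-level CSV files into a staging directory.
[global]
input_root = "data"

[template.level_1]
conditions = ["is_csv"]
actions = [["copy_to", "out/csv_copies"]]
counteractions = ["warn"]
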