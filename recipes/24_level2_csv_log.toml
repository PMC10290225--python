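# Log every CSV found exactly two levels below the root.
[global]
input_root = "data"

[template.level_2]
conditions = ["is_csv"]
actions = [["log_to_file", "out/level2_csv.txt"]]
counteractions = ["warn"]
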