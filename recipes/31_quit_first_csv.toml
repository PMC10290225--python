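# Stop traversal at the first CSV file.
[global]
input_root = "data"

[template.any]
conditions = ["is_csv"]
actions = [["log_to_file", "out/first_csv.txt"], "quit"]
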