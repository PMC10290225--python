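# Disjunctive condition list: CSV or image.
[global]
input_root = "data"

[template.any]
conditions = ["is_csv", "is_image"]
condition_mode = "any"
actions = [["log_to_file", "out/content_files.txt"]]
counteractions = ["warn"]
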