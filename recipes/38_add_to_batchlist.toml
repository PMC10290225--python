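# Rule-driven aggregation: matched nodes feed a batch list.
[global]
input_root = "data"

[[global.aggregators]]
name = "batch"
filter = "never"
map = "path"
reduce = "list_paths"
sink = { kind = "text_list", destination = "out/batch.txt" }

[template.any]
conditions = ["is_csv"]
actions = [["add_to_list", "batch"]]
counteractions = ["warn"]
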