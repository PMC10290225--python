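# Count files within a size window.
[global]
input_root = "data"

[[global.aggregators]]
name = "mid_sized"
filter = ["all_of", "is_file", ["size_at_least", 32], ["size_at_most", 128]]
map = "path"
reduce = "count"
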