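# Count hidden entries (they are traversed, not skipped).
[global]
input_root = "data"

[[global.aggregators]]
name = "hidden_count"
filter = "is_hidden"
map = "path"
reduce = "count"
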