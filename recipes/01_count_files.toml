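# Count every file in the tree.
[global]
input_root = "data"

[[global.aggregators]]
name = "file_count"
filter = "is_file"
map = "path"
reduce = "count"
sink = "stdout"
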