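# Bottom-up traversal (contents before their directory).
[global]
input_root = "data"
traversal_order = "bottomup"

[[global.aggregators]]
name = "file_count"
filter = "is_file"
map = "path"
reduce = "count"
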