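# Minimal counting recipe: file count plus total bytes, no rule blocks.
[global]
input_root = "data"

[[global.aggregators]]
name = "file_count"
filter = "is_file"
map = "path"
reduce = "count"
sink = "stdout"

[[global.aggregators]]
name = "total_bytes"
filter = "is_file"
map = "size"
reduce = "sum_size"
sink = "stdout"
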