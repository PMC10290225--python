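# Parallel execution with worker-local aggregation shards.
[global]
input_root = "data"
parallel = true
workers = 4

[[global.aggregators]]
name = "file_count"
filter = "is_file"
map = "path"
reduce = "count"

[[global.aggregators]]
name = "total_bytes"
filter = "is_file"
map = "size"
reduce = "sum_size"
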