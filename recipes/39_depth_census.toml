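# Node counts per hierarchy level.
[global]
input_root = "data"

[[global.aggregators]]
name = "depth1"
filter = ["path_depth_is", 1]
map = "path"
reduce = "count"

[[global.aggregators]]
name = "depth2"
filter = ["path_depth_is", 2]
map = "path"
reduce = "count"

[[global.aggregators]]
name = "depth3"
filter = ["path_depth_is", 3]
map = "path"
reduce = "count"
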