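# Count entries whose stem is a pure integer.
[global]
input_root = "data"

[[global.aggregators]]
name = "integer_named"
filter = "name_is_integer"
map = "path"
reduce = "count"
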