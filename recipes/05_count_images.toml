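[global]
input_root = "data"

[[global.aggregators]]
name = "image_count"
filter = "is_image"
map = "path"
reduce = "count"
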