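# Reusable alias from the global section.
[global]
input_root = "data"

[global.shared_definitions]
is_picture = ["any_of", ["has_extension", ".png"], ["has_extension", ".tif"]]

[[global.aggregators]]
name = "picture_count"
filter = "is_picture"
map = "path"
reduce = "count"

[template.any]
conditions = [["any_of", "is_dir", "not is_picture", ["size_at_least", 1]]]
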