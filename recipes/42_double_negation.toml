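# not(not(is_file)) is is_file: composite nesting sanity contract.
[global]
input_root = "data"

[[global.aggregators]]
name = "file_count"
filter = ["not", ["not", "is_file"]]
map = "path"
reduce = "count"

[template.any]
conditions = [["any_of", ["not", ["not", "is_file"]], "is_dir"]]
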