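# Batch list of files of at least 64 bytes.
[global]
input_root = "data"

[[global.aggregators]]
name = "large_files"
filter = ["all_of", "is_file", ["size_at_least", 64]]
map = "path"
reduce = "list_paths"
sink = { kind = "text_list", destination = "out/large_files.txt" }
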