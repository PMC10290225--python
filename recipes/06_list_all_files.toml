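# Sorted list of every file path, written as a text list.
[global]
input_root = "data"

[[global.aggregators]]
name = "all_files"
filter = "is_file"
map = "path"
reduce = "list_paths"
sink = { kind = "text_list", destination = "out/all_files.txt" }
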