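[global]
input_root = "data"

[[global.aggregators]]
name = "png_files"
filter = ["has_extension", ".png"]
map = "path"
reduce = "list_paths"
sink = { kind = "text_list", destination = "out/png_files.txt" }
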