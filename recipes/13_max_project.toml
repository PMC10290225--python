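# Maximum intensity projection over the z-slice series.
[global]
input_root = "data"
regex_enabled = true

[[global.aggregators]]
name = "mip"
filter = ["name_matches", 'z\d+\.png']
map = "image"
reduce = "max_project"
sort_key = 'z(\d+)'
sink = { kind = "image_file", destination = "out/mip.tif" }
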