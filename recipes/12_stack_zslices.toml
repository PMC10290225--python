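# Stack z-numbered 2D slices into a 3D volume (natural sort: z2 < z10).
[global]
input_root = "data"
regex_enabled = true

[[global.aggregators]]
name = "zstack"
filter = ["name_matches", 'z\d+\.png']
map = "image"
reduce = "stack_images"
sort_key = 'z(\d+)'
sink = { kind = "image_file", destination = "out/volume.tif" }
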