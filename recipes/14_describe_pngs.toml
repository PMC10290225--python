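# Per-slice intensity statistics and object metrics over all PNG images.
[global]
input_root = "data"

[[global.aggregators]]
name = "png_stats"
filter = ["has_extension", ".png"]
map = "image"
reduce = "describe_images"
sink = { kind = "csv_table", destination = "out/png_stats.csv" }
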