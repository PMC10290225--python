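# Colocalization metrics between the two channel images.
[global]
input_root = "data"
regex_enabled = true

[[global.aggregators]]
name = "coloc"
filter = ["name_matches", 'ch\d\.png']
map = "image"
reduce = "coloc"
sink = { kind = "csv_table", destination = "out/coloc.csv" }
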