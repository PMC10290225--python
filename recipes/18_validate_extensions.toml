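# Every file carries one of the sanctioned lowercase extensions.
[global]
input_root = "data"
regex_enabled = true

[template.any]
conditions = [["any_of", "is_dir", ["name_matches", '.*\.(dat|png|tif|csv)']]]
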