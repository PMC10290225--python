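# The first level should hold directories; warn about stray files.
[global]
input_root = "data"

[template.level_1]
conditions = ["is_dir"]
counteractions = ["warn"]
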