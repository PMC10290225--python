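# Move opaque .dat files out of the tree.
[global]
input_root = "data"

[template.any]
conditions = [["has_extension", ".dat"]]
actions = [["move_to", "out/dat"]]
counteractions = ["warn"]
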