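# Flag oversized files instead of failing validation.
[global]
input_root = "data"

[template.any]
conditions = [["any_of", "is_dir", ["size_at_most", 4096]]]
counteractions = ["warn"]
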