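# Quarantine stray .tmp files (reversible removal).
[global]
input_root = "data"

[template.any]
conditions = [["not has_extension", ".tmp"]]
counteractions = ["remove"]
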