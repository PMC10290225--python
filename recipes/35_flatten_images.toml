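# Flatten every image into one directory under path-derived names.
[global]
input_root = "data"

[template.any]
conditions = ["is_image"]
actions = [["flatten_to", "out/flat"]]
counteractions = ["warn"]
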