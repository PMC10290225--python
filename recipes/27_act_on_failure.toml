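# Inverted firing: actions run on nodes that FAIL the conditions.
[global]
input_root = "data"
act_on_success = false

[template.any]
conditions = [["has_extension", ".xyz"]]
actions = ["warn"]
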