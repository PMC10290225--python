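# Names must not contain whitespace.
[global]
input_root = "data"
regex_enabled = true

[template.any]
conditions = [["not name_matches", '.*\s.*']]
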