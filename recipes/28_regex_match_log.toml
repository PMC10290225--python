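# Pattern-matched capture into a log file.
[global]
input_root = "data"
regex_enabled = true

[template.any]
conditions = [["name_matches", 'img\d+\.png']]
actions = [["log_to_file", "out/matched_images.txt"]]
counteractions = ["warn"]
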