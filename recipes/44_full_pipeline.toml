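# Counting, batch listing and validation in a single recipe.
[global]
input_root = "data"
regex_enabled = true

[[global.aggregators]]
name = "file_count"
filter = "is_file"
map = "path"
reduce = "count"

[[global.aggregators]]
name = "csv_list"
filter = "is_csv"
map = "path"
reduce = "list_paths"
sink = { kind = "text_list", destination = "out/pipeline_csvs.txt" }

[template.any]
conditions = [["any_of", "is_dir", ["name_matches", '[\x20-\x7e]+']]]
counteractions = ["warn"]
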