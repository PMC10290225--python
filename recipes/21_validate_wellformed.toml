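# The full layout contract: clean names, sanctioned extensions,
# conforming CSV schemas and 3D TIFF volumes.
[global]
input_root = "data"
regex_enabled = true

[template.any]
conditions = [
  ["any_of",
    "is_dir",
    ["all_of",
      ["not name_matches", '.*\s.*'],
      "not is_hidden",
      ["name_matches", '[\x20-\x7e]+'],
      ["name_matches", '.*\.(dat|png|tif|csv)'],
      ["any_of", "not is_csv", ["csv_has_columns", "x", "y", "z"]],
      ["any_of", ["not has_extension", ".tif"], ["image_has_dims", 3]]
    ]
  ]
]
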