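# TIFF files are expected to hold 3D volumes.
[global]
input_root = "data"

[template.any]
conditions = [["any_of", ["not has_extension", ".tif"], ["image_has_dims", 3]]]
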