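{
  "name": "bet-like brain extraction",
  "id": "bet",
  "description": "Flat (classic-style) descriptor: positional input/output plus optional flags.",
  "tool-version": "6.0",
  "command-line": "bet [INPUT] [OUTPUT] [BINARY_MASK] [FRACTIONAL_INTENSITY]",
  "container-image": {"type": "docker", "image": "example/neuro-tools", "tag": "6.0"},
  "inputs": [
    {"id": "input", "description": "Input volume", "type": "File", "value-key": "[INPUT]"},
    {"id": "output", "description": "Output basename", "type": "String", "value-key": "[OUTPUT]"},
    {
      "id": "binary_mask",
      "description": "Also write a binary brain mask",
      "type": "Flag",
      "command-line-flag": "-m",
      "value-key": "[BINARY_MASK]",
      "optional": true
    },
    {
      "id": "fractional_intensity",
      "description": "Fractional intensity threshold",
      "type": "Number",
      "command-line-flag": "-f",
      "value-key": "[FRACTIONAL_INTENSITY]",
      "optional": true,
      "minimum": 0,
      "maximum": 1
    }
  ],
  "output-files": [
    {"id": "outfile", "description": "Extracted brain", "path-template": "[OUTPUT].nii.gz"},
    {"id": "mask_file", "description": "Binary mask", "path-template": "[OUTPUT]_mask.nii.gz", "optional": true}
  ]
}
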