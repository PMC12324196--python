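{
  "name": "interp-like resampler",
  "id": "interp_like",
  "description": "Alternation example: a required interpolation method chosen from mutually exclusive alternatives.",
  "command-line": "resample [INPUT] [METHOD] [OUTPUT]",
  "inputs": [
    {"id": "input", "description": "Input volume", "type": "File", "value-key": "[INPUT]"},
    {
      "id": "method",
      "description": "Interpolation method",
      "value-key": "[METHOD]",
      "type": [
        {"id": "linear", "description": "Trilinear interpolation", "command-line": "Linear", "inputs": []},
        {
          "id": "bspline",
          "description": "B-spline interpolation",
          "command-line": "BSpline [ORDER]",
          "inputs": [
            {"id": "order", "description": "Spline order", "type": "Number", "integer": true,
             "value-key": "[ORDER]", "minimum": 1, "maximum": 5}
          ]
        },
        {
          "id": "label",
          "description": "Smoothed label interpolation",
          "command-line": "GenericLabel [SIGMA]",
          "inputs": [
            {"id": "sigma", "description": "Smoothing sigma", "type": "Number", "value-key": "[SIGMA]"}
          ]
        }
      ]
    },
    {"id": "output", "description": "Output name", "type": "String", "value-key": "[OUTPUT]"}
  ],
  "output-files": [
    {"id": "resampled", "description": "Resampled volume", "path-template": "[OUTPUT].nii.gz"}
  ]
}
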