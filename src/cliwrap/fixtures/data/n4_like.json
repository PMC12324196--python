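{
  "name": "n4-like bias field correction",
  "id": "n4_like",
  "description": "Hierarchy example: an optional nested --convergence subcommand whose iteration counts join into a single x-separated token.",
  "command-line": "n4correct -i [INPUT] -o [OUTPUT] [CONVERGENCE]",
  "inputs": [
    {"id": "input", "description": "Input volume", "type": "File", "value-key": "[INPUT]"},
    {"id": "output", "description": "Corrected output name", "type": "String", "value-key": "[OUTPUT]"},
    {
      "id": "convergence",
      "description": "Convergence criteria",
      "value-key": "[CONVERGENCE]",
      "optional": true,
      "type": {
        "id": "convergence",
        "command-line": "--convergence [ITERS] [TOL]",
        "inputs": [
          {
            "id": "iters",
            "description": "Iterations per resolution level, joined with 'x'",
            "type": "Number",
            "integer": true,
            "list": true,
            "optional": true,
            "list-separator": "x",
            "value-key": "[ITERS]"
          },
          {
            "id": "tol",
            "description": "Convergence tolerance",
            "type": "Number",
            "optional": true,
            "value-key": "[TOL]"
          }
        ]
      }
    }
  ],
  "output-files": [
    {
      "id": "corrected",
      "description": "Bias-corrected volume",
      "path-template": "[INPUT]_corrected.nii.gz",
      "path-template-stripped-extensions": [".nii", ".nii.gz"]
    }
  ]
}
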