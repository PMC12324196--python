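{
  "name": "toycalc",
  "id": "toycalc",
  "description": "Toy image calculator: an input file, zero or more chained operations (each with its own parameters), and an output. Operation order is significant.",
  "tool-version": "1.0.0",
  "command-line": "toycalc [INPUT] [OPS] [OUTPUT]",
  "inputs": [
    {
      "id": "input",
      "description": "Input image",
      "type": "File",
      "value-key": "[INPUT]"
    },
    {
      "id": "ops",
      "description": "Operation chain; emitted in the order supplied",
      "value-key": "[OPS]",
      "optional": true,
      "list": true,
      "type": [
        {
          "id": "add",
          "description": "Add a constant",
          "command-line": "-add [VALUE]",
          "inputs": [
            {"id": "value", "description": "Constant to add", "type": "Number", "value-key": "[VALUE]"}
          ]
        },
        {
          "id": "sub",
          "description": "Subtract a constant",
          "command-line": "-sub [VALUE]",
          "inputs": [
            {"id": "value", "description": "Constant to subtract", "type": "Number", "value-key": "[VALUE]"}
          ]
        },
        {
          "id": "complex",
          "description": "Nested operation with mutually exclusive modes",
          "command-line": "-complex [MODE]",
          "inputs": [
            {
              "id": "mode",
              "description": "Operation mode",
              "value-key": "[MODE]",
              "type": [
                {
                  "id": "option1",
                  "command-line": "option1 [PARAM1]",
                  "inputs": [
                    {"id": "param1", "type": "String", "value-key": "[PARAM1]"}
                  ]
                },
                {
                  "id": "option2",
                  "command-line": "option2 [PARAM1] [PARAM2]",
                  "inputs": [
                    {"id": "param1", "type": "String", "value-key": "[PARAM1]"},
                    {"id": "param2", "type": "String", "value-key": "[PARAM2]"}
                  ]
                }
              ]
            }
          ]
        }
      ]
    },
    {
      "id": "output",
      "description": "Output image name",
      "type": "String",
      "value-key": "[OUTPUT]"
    }
  ],
  "output-files": [
    {"id": "out_file", "description": "Result image", "path-template": "[OUTPUT]"}
  ]
}
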