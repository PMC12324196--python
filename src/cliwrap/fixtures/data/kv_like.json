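{
  "name": "kv-like metadata tagger",
  "id": "kv_like",
  "description": "Repetition example: arbitrary repeated -set key value pairs. Values may contain spaces, leading dashes, or unicode (süße Grüße) and must survive verbatim.",
  "command-line": "kvtool [INPUT] [ENTRIES] [OUTPUT]",
  "inputs": [
    {"id": "input", "description": "Input file", "type": "File", "value-key": "[INPUT]"},
    {
      "id": "entries",
      "description": "Key-value pairs, repeated in order",
      "value-key": "[ENTRIES]",
      "optional": true,
      "list": true,
      "type": {
        "id": "entry",
        "command-line": "-set [KEY] [VAL]",
        "inputs": [
          {"id": "key", "description": "Metadata key", "type": "String", "value-key": "[KEY]"},
          {"id": "val", "description": "Metadata value", "type": "String", "value-key": "[VAL]"}
        ]
      }
    },
    {"id": "output", "description": "Output file name", "type": "String", "value-key": "[OUTPUT]"}
  ],
  "output-files": [
    {"id": "tagged", "description": "Tagged copy", "path-template": "[OUTPUT].json"}
  ]
}
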