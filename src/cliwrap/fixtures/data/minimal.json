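{
  "name": "true",
  "id": "minimal_true",
  "description": "Smallest valid interface: a bare executable, no parameters, no outputs.",
  "command-line": "true",
  "inputs": [],
  "output-files": []
}
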