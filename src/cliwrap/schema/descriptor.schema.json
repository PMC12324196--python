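{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/cliwrap/descriptor.schema.json",
  "title": "cliwrap extended tool descriptor",
  "description": "Extended Boutiques dialect: classic flat descriptors parse unchanged; an input's 'type' may also be a subcommand object (hierarchy) or an array of >=2 subcommand objects (alternation), and 'list': true on such inputs allows repetition. Unknown fields are preserved verbatim but carry no semantics.",
  "type": "object",
  "required": ["name", "command-line"],
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "id": {"type": "string"},
    "description": {"type": "string"},
    "author": {"anyOf": [{"type": "string"}, {"type": "array", "items": {"type": "string"}}]},
    "url": {"type": "string"},
    "tool-version": {"type": "string"},
    "command-line": {
      "type": "string",
      "minLength": 1,
      "description": "Whitespace-separated tokens; a token exactly equal to an input's value-key is a placeholder, everything else is a literal. The first token must be a literal (the executable). Value-keys embedded inside longer tokens are rejected."
    },
    "container-image": {
      "type": "object",
      "required": ["image"],
      "properties": {
        "type": {"type": "string"},
        "image": {"type": "string", "minLength": 1},
        "tag": {"type": "string"}
      }
    },
    "inputs": {"type": "array", "items": {"$ref": "#/$defs/input"}},
    "output-files": {"type": "array", "items": {"$ref": "#/$defs/output"}},
    "groups": {"type": "array", "items": {"$ref": "#/$defs/group"}}
  },
  "$defs": {
    "input": {
      "type": "object",
      "required": ["id"],
      "properties": {
        "id": {"type": "string", "pattern": "^[A-Za-z][A-Za-z0-9_]*$"},
        "name": {"type": "string"},
        "description": {"type": "string"},
        "value-key": {"type": "string", "pattern": "^\\[[A-Z0-9_]+\\]$"},
        "type": {
          "description": "String|File|Number|Flag, or a subcommand object, or an array of >=2 subcommand objects (mutually exclusive alternatives)",
          "anyOf": [
            {"enum": ["String", "File", "Number", "Flag"]},
            {"$ref": "#/$defs/subcommand"},
            {"type": "array", "minItems": 2, "items": {"$ref": "#/$defs/subcommand"}}
          ]
        },
        "integer": {"type": "boolean", "description": "with type Number: integer-valued"},
        "optional": {"type": "boolean"},
        "list": {"type": "boolean", "description": "repeatable; requires optional (zero occurrences are legal)"},
        "list-separator": {"type": "string", "description": "join list elements into one token (scalar lists only)"},
        "command-line-flag": {"type": "string", "minLength": 1},
        "default-value": {},
        "value-choices": {"type": "array"},
        "minimum": {"type": "number"},
        "maximum": {"type": "number"}
      }
    },
    "subcommand": {
      "type": "object",
      "required": ["id", "command-line"],
      "properties": {
        "id": {"type": "string", "pattern": "^[A-Za-z][A-Za-z0-9_]*$"},
        "description": {"type": "string"},
        "command-line": {"type": "string", "minLength": 1},
        "inputs": {"type": "array", "items": {"$ref": "#/$defs/input"}}
      },
      "description": "Nesting depth is capped at 10 levels."
    },
    "output": {
      "type": "object",
      "required": ["id", "path-template"],
      "properties": {
        "id": {"type": "string", "pattern": "^[A-Za-z][A-Za-z0-9_]*$"},
        "description": {"type": "string"},
        "path-template": {
          "type": "string",
          "minLength": 1,
          "description": "Literals plus value-key references to file/string inputs; file values contribute their basename with the longest matching stripped extension removed"
        },
        "path-template-stripped-extensions": {
          "type": "array",
          "items": {"type": "string", "pattern": "^\\."}
        },
        "optional": {"type": "boolean"}
      }
    },
    "group": {
      "type": "object",
      "required": ["id", "members"],
      "properties": {
        "id": {"type": "string"},
        "members": {"type": "array", "items": {"type": "string"}},
        "mutually-exclusive": {"type": "boolean"},
        "one-is-required": {"type": "boolean"}
      },
      "description": "Assignment-time constraints only; groups never change argv construction"
    }
  }
}
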