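"""Reserved identifier lists for every shipped dialect profile.

Mangling must avoid the union of all lists so one IR serves every backend.
"""

PYTHON_RESERVED = frozenset({
    "False", "None", "True", "and", "as", "assert", "async", "await",
    "break", "class", "continue", "def", "del", "elif", "else", "except",
    "finally", "for", "from", "global", "if", "import", "in", "is",
    "lambda", "nonlocal", "not", "or", "pass", "raise", "return", "try",
    "while", "with", "yield",
    # soft keywords and shim names worth avoiding in generated signatures
    "match", "case", "type", "runner", "execution", "cargs",
})

R_RESERVED = frozenset({
    "if", "else", "repeat", "while", "function", "for", "next", "break",
    "TRUE", "FALSE", "NULL", "Inf", "NaN", "NA", "NA_integer_",
    "NA_real_", "NA_character_", "in",
    "runner", "execution", "cargs",
})

ALL_RESERVED = frozenset(w.lower() for w in PYTHON_RESERVED | R_RESERVED)
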