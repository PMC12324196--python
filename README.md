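# cliwrap

A compiler and runtime for command-line tool descriptors, aimed at the
scientific packages — neuroimaging and bioinformatics above all — whose
power lives behind complex, heterogeneous CLIs.  A tool's interface is
written once as a JSON descriptor; `cliwrap` validates it, lowers it to a
language-agnostic intermediate representation (IR), and either interprets
it directly (the reference semantics) or compiles it into typed,
documented wrapper functions for the shipped dialect profiles (Python and
R).  A decoupled runner layer executes the resulting argv token lists —
dry-run, local process, or an engine-agnostic container mount plan — and
records provenance as file-dependency graphs.

## The interface model

Classic flat Boutiques-style descriptors parse unchanged: a `command-line`
template whose `[VALUE_KEY]` tokens reference typed `inputs`, plus
`output-files` path templates and optional container metadata.  On top of
this, one extension rule makes the dialect expressive enough for real
scientific CLIs while staying a *regular* language: an input's `type` may
itself be a nested command object (**hierarchy**), an array of ≥2 such
objects (**alternation**, mutually exclusive), and `"list": true` on such
an input allows it to repeat (**repetition**).

The shipped `toycalc` fixture combines all three.  Its grammar, in the
usual production-rule notation (⟨…⟩ = required parameter, ε = empty):

```
A → ⟨input⟩ B ⟨output⟩
B → ε | C B
C → -add ⟨value⟩ | -sub ⟨value⟩ | -complex F
F → option1 ⟨param1⟩ | option2 ⟨param1⟩ ⟨param2⟩
```

i.e. an input file, zero or more operations (each with its own
parameters), and an output.  `interpreter.derives` is a brute-force
bounded membership oracle for exactly this grammar view of a descriptor;
the test suite uses it to certify every argv the pipeline emits.

## Worked example

```python
from cliwrap import lower, optimize, build_cargs, resolve_outputs
from cliwrap.fixtures import fixture_descriptor

ir = optimize(lower(fixture_descriptor("toycalc")))
a = {"input": "in.nii",
     "ops": [{"add": {"value": 5}}, {"sub": {"value": 3}}],
     "output": "out.nii"}
print(build_cargs(ir, a))
print(resolve_outputs(ir, a, root="toycalc_1").files)
```

prints

```
['toycalc', 'in.nii', '-add', '5', '-sub', '3', 'out.nii']
{'out_file': 'out.nii'}
```

— the argv token list (final; nothing downstream ever re-splits or
shell-interprets it) and the resolved output paths relative to the
execution's output root.  Compiling the same descriptor
(`cliwrap compile descs/ --target host --out gen/`) produces a
`toycalc(input, output, ops=None, runner=None)` function whose dry-run
emits the identical token list, with union alternatives exposed as typed
constructors (`toycalc_ops_add(value=5)`), and a named-tuple result
carrying `root` and `out_file`.  The `companion` target emits the same
interface in R.

From a shell:

```sh
cliwrap run descs/toycalc.json --params params.json --dry-run   # one token per line
cliwrap graph session_dir/                                      # DOT dependency graph
```

## Layout

| Path | Contents |
| --- | --- |
| `src/cliwrap/model.py` | descriptor dialect: parse, validate, serialize |
| `src/cliwrap/ir.py` | lowering, optimization, identifier mangling |
| `src/cliwrap/interpreter.py` | reference argv/output semantics + grammar oracle |
| `src/cliwrap/codegen/` | dialect profiles (data), emitter, descriptor backend |
| `src/cliwrap/runtime.py` | runners, container plans, dependency graphs |
| `src/cliwrap/fixtures/` | authored descriptors + seeded random generators |
| `src/cliwrap/schema/` | JSON Schema defining the dialect |
| `docs/methods.md` | design and semantics notes |
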