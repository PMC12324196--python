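# Methods and design notes

## The model

A descriptor is a grammar for one tool's command line.  We deliberately
restrict the dialect to a **regular** language: a descriptor's nesting is
finite structure (hierarchy), alternatives are a finite union
(alternation), and lists are Kleene-style repetition — there is no
self-reference, and a validation cap of 10 nesting levels makes the bound
explicit.  Regularity is what keeps every downstream component simple:
argv construction is a single left-to-right walk, membership checking is
decidable by bounded exhaustive derivation, and generated wrappers are
straight-line code with loops and branches only.

Three layers share one semantics:

1. **Interpreter** (`interpreter.build_cargs`) — the reference.  Flags
   emit their token only on `True`; valued parameters emit an optional
   flag token then the formatted value; repeatable parameters emit
   elements in the order supplied (operation chains are order-sensitive,
   as in `fslmaths`-style tools); unions dispatch on the alternative id;
   an alternative emits a discriminator literal only if its own template
   says so.  Unbound optionals emit nothing; `false` flags and unbound
   flags are indistinguishable.
2. **Generated wrappers** — compiled, not interpreted: the emitter walks
   the IR once and writes explicit `append`/loop/branch statements through
   a dialect profile's syntax atoms.  The oracle-equivalence suite holds
   wrapper dry-run argv equal to the interpreter's, token for token, over
   seeded corpora; the two routes share no argv-construction code (the
   generated shim reimplements only value formatting and path helpers).
3. **`derives`** — a test-only brute-force membership oracle.  It tracks
   the set of token positions reachable after each plan step; repetition
   is a reachability closure, nesting recurses up to `depth_cap`.
   Terminals are typed: an integer slot only matches an integer-shaped
   token within its bounds, a choice-constrained slot only matches a
   choice.  This is what makes single-token deletions from the worked
   example all rejectable: a dangling `-add` cannot swallow `-sub`
   because `-sub` is not a number.

## Argv and path conventions

* Tokens are final.  No shell ever sees them; spaces, leading dashes and
  non-ASCII pass through verbatim (pinned by the `kv_like` fixture and
  local-runner tests).
* Numbers: integers render without a decimal point; floats use the
  shortest round-trip decimal (`repr` in the host dialect).  The R shim
  renders integral doubles without a decimal point because R does not
  distinguish `5` from `5.0` at JSON boundaries; a *non-integral* double
  relies on R's default 7-significant-digit formatting, which agrees with
  the host on the value ranges the corpora use but is not guaranteed to
  agree on pathological doubles.  Cross-dialect agreement is therefore
  certified by golden files plus a live smoke test on the worked example,
  not by a floating-point corpus.
* File values pass through argv verbatim (relative or absolute); basename
  extraction happens only inside output path templates, where the longest
  matching listed suffix is also stripped.  Whether directories should
  survive into resolved output names was genuinely open; basename-only is
  the decision here and is isolated behind `resolve_outputs`.
* Output roots are `<workdir>/<uid>_<seq>` — collision-free provenance
  with zero configuration.

## Assignments

Assignments are JSON-shaped dicts keyed by parameter id: lists for
repeatable parameters (empty = zero occurrences, always legal), nested
dicts for subcommands, one-key `{alternative: {...}}` dicts for unions.
`check_assignment` is the single gate: required/typed/choice/bound checks,
union-tag validity, and group constraints (mutual exclusion,
one-required).  Groups deliberately never affect argv — they are
validation predicates only, because the dialect gives them no emission
semantics.  Defaults are materialized in the IR, so the interpreter,
every generated dialect, and the emitted-descriptor round-trip agree on
them without consulting the source document.

## Optimization

Exactly four rewrites, each trivially semantics-preserving and idempotent:
merge adjacent literal parts within a token recipe, drop empty recipes,
hoist single-alternative unions to plain subcommands (such IR only arises
programmatically — the validator requires ≥2 alternatives), and
deduplicate mangled names defensively.  Nothing else is applied: any new
rewrite must pass the argv-equivalence property suite, which compares
optimized and unoptimized IR over the full seeded corpus.

## IR debug dump

`ir.ir_to_debug_dict` serializes an IR for inspection (not a public
interchange format): `{"uid", "plan", "params", "outputs"}`, where a plan
is `{"cargs": [[{"lit": …} | {"ref": <path>}, …], …], "params": [<path>, …]}`,
each entry of `params` carries `legal_name`, `type`, `optional`,
`repeatable`, optional `default`/`flag`, and nested plans keyed by
alternative id; outputs list their template parts with `strip` suffix
lists.  Paths are the "/"-joined ids used everywhere in diagnostics.

## Runners and provenance

The runner contract is three methods (`translate_input`, `output_root`,
`run`) behind `new_execution`; dry-run and local runners ship, and the
container *plan* — read-only input mounts at `/cliwrap_input/<k>/<basename>`,
one writable `/cliwrap_output`, argv rewritten onto mount paths — is
produced for inspection without ever invoking an engine.  Engine spawning
stays behind the same contract (exercised with mocks in tests), keeping
the suite runnable on machines without a container daemon.  Process
output always goes to per-execution log files.  Dependency-graph edges
are exactly the (producer, consumer, path) triples where a consumer input
equals an earlier producer's resolved output; the test oracle is an
independent O(n²) pairwise intersection.  The timing middleware is an
experimental stub: wall-clock only, interface not stable.

## Synthetic corpus

`fixtures.random_descriptor` emulates the structural variety of real
scientific CLIs: all scalar kinds, flags, choices and bounds, defaults,
joined lists (`50x20x10`-style), nested subcommands, unions and repeated
subcommands, with ≥10% each of union/subcommand/repeatable slots over the
default corpus and value pools that include spaces, leading dashes and
unicode.  Descriptors are valid and assignments check clean by
construction, so the property suites run without rejection sampling.
What the generator does **not** emulate: adversarial identifier
collisions across packages, deeply pathological float values, multi-file
content semantics, or any behavior of the wrapped tools themselves —
passing suites certify interface semantics, not that a wrapped tool
computes anything.  Corpus sizes (100×5 equivalence pairs, 200 round-trip
seeds, 60 container plans) were chosen as comfortable desk-scale defaults
with fully deterministic seeding.

## Degenerate inputs and tie-breaks

* The empty interface (`minimal`) is a first-class case everywhere.
* A parameter bound to `null` is treated as unbound; a defaulted
  parameter can therefore never emit "nothing" unless its default is
  itself null.
* Mangling: lowercase, collapse non-alphanumerics, `v_` prefix for a
  leading digit, `_` suffix for words reserved in *any* shipped dialect,
  `_2`/`_3`… for collisions — deterministic and injective per scope.
  Generated helper/temporary names end in `_` after a digit or keyword
  stem, a shape mangling cannot produce, so they never shadow parameters.
* `derives` with `depth_cap < 1` is an error; the cap bounds nested
  recursion, not repetition counts (those are bounded by the token list).

## Known limitations

* The membership oracle is mildly permissive inside multi-part token
  recipes (regex-level typing, no bound checks) — those recipes cannot be
  written in the JSON dialect and arise only from programmatic IR.
* The R dialect accepts integral doubles as integers (see above).
* Container plans rewrite argv tokens that exactly equal an input path;
  a file path embedded inside a joined token is not rewritten (the
  synthetic corpus keeps file parameters out of joined lists, and real
  descriptors that join file lists should expect host paths inside the
  joined token).
* Unknown JSON fields survive round-trips but are semantically inert; no
  extension mechanism interprets them.
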