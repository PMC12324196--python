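"""Dialect profiles: data-driven descriptions of code-generation targets.

A profile carries no executable logic — only syntax atoms (string templates
with named slots), the reserved-word list, block punctuation, and the text
of the dialect's runtime shim.  The emitter walks the IR once and renders
through whichever profile it is handed, so adding a dialect means writing a
new profile, not touching the compiler core.

Two profiles ship: ``host`` (Python, the implementation's own dialect) and
``companion`` (R).  Generated wrappers depend only on their shim file, never
on this package, so a generated tree is a standalone artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..reserved import PYTHON_RESERVED, R_RESERVED

#: every template slot the emitter may request; generate() verifies presence
REQUIRED_TEMPLATES = (
    "module_header", "comment", "func_def", "if", "elif", "else", "for",
    "return", "assign", "append", "extend", "cargs_init", "call", "kwarg",
    "dict_item", "dict_new", "vec_lit", "not_null", "is_null", "truthy_flag",
    "truthy_list", "and", "eq", "tag_get", "key_get", "fmt_call",
    "translate_call", "join_list", "concat", "join_path", "part_call",
    "record_new", "runner_default", "new_execution", "run_call",
    "output_root", "ternary", "null", "true", "false",
)


@dataclass(frozen=True)
class DialectProfile:
    name: str
    file_extension: str
    indent: str
    block_end: str           # "" for indentation-scoped, "}" for braces
    doc_inside: bool         # docs inside the function body vs above it
    doc_open: str
    doc_line: str
    doc_close: str
    reserved: frozenset[str]
    shim_filename: str
    shim_source: str
    templates: dict[str, str] = field(default_factory=dict)
    record_def: str = ""     # optional: named-record type definition


# --------------------------------------------------------------------------
# host profile: Python
# --------------------------------------------------------------------------

_PY_SHIM = '''"""Shared runtime shim for generated wrappers (standalone, no deps).

Any object with ``new_execution(metadata)`` returning an execution that
offers ``translate_input(path)``, ``output_root()`` and ``run(cargs)`` can
act as a runner; :class:`DryRunner` is the built-in default and never
spawns a process.
"""

import posixpath


def fmt_value(v):
    """Integers render without a decimal point; floats use shortest repr."""
    if isinstance(v, bool):
        raise TypeError("booleans are flag-only")
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def join_path(*parts):
    return posixpath.join(*parts)


def _strip_suffix(name, suffixes):
    best = ""
    for s in suffixes:
        if name.endswith(s) and len(s) > len(best):
            best = s
    return name[: len(name) - len(best)] if best else name


def template_part(value, is_file, strip):
    s = fmt_value(value)
    if is_file:
        s = posixpath.basename(s)
    return _strip_suffix(s, strip)


class _DryExecution:
    def __init__(self, runner, metadata, seq):
        self._runner = runner
        self._metadata = metadata
        self._seq = seq

    def translate_input(self, path):
        return path

    def output_root(self):
        return "%s_%d" % (self._metadata.get("uid", "tool"), self._seq)

    def run(self, cargs):
        self._runner.last_cargs = list(cargs)
        self._runner.records.append(
            {"seq": self._seq, "uid": self._metadata.get("uid"), "cargs": list(cargs)})
        return 0


class DryRunner:
    """Records argv instead of executing; the decoupled-execution default."""

    def __init__(self):
        self.records = []
        self.last_cargs = None
        self._seq = 0

    def new_execution(self, metadata):
        self._seq += 1
        return _DryExecution(self, metadata, self._seq)


def default_runner():
    return DryRunner()
'''

HOST = DialectProfile(
    name="host",
    file_extension=".py",
    indent="    ",
    block_end="",
    doc_inside=True,
    doc_open='"""{first}',
    doc_line="{text}",
    doc_close='"""',
    reserved=frozenset(PYTHON_RESERVED),
    shim_filename="cliwrap_shim.py",
    shim_source=_PY_SHIM,
    record_def='{rec} = collections.namedtuple("{rec}", [{fields}])',
    templates={
        "module_header": "import collections\n\nfrom cliwrap_shim import DryRunner, default_runner, fmt_value, join_path, template_part",
        "comment": "# {text}",
        "func_def": "def {name}({args}):",
        "if": "if {cond}:",
        "elif": "elif {cond}:",
        "else": "else:",
        "for": "for {var} in {seq}:",
        "return": "return {value}",
        "assign": "{name} = {value}",
        "append": "cargs.append({value})",
        "extend": "cargs.extend({value})",
        "cargs_init": "cargs = []",
        "call": "{fn}({args})",
        "kwarg": "{name}={value}",
        "dict_item": '"{key}": {value}',
        "dict_new": "{{{items}}}",
        "vec_lit": "[{items}]",
        "not_null": "{value} is not None",
        "is_null": "{value} is None",
        "truthy_flag": "{value}",
        "truthy_list": "{value}",
        "and": "{a} and {b}",
        "eq": "{a} == {b}",
        "tag_get": '{value}["__tag"]',
        "key_get": '{value}.get("{key}")',
        "fmt_call": "fmt_value({value})",
        "translate_call": "execution.translate_input({value})",
        "join_list": "{sep}.join([fmt_value(_e) for _e in {value}])",
        "concat": '"".join([{items}])',
        "join_path": "join_path({items})",
        "part_call": "template_part({value}, {is_file}, {strip})",
        "record_new": "{rec}({kwargs})",
        "runner_default": "runner = runner if runner is not None else default_runner()",
        "new_execution": "execution = runner.new_execution({meta})",
        "run_call": "execution.run(cargs)",
        "output_root": "execution.output_root()",
        "ternary": "({then}) if ({cond}) else ({other})",
        "null": "None",
        "true": "True",
        "false": "False",
    },
)


# --------------------------------------------------------------------------
# companion profile: R
# --------------------------------------------------------------------------

_R_SHIM = '''# Shared runtime shim for generated wrappers (standalone, base R only).
#
# A runner is an environment with new_execution(metadata); an execution is an
# environment with translate_input(path), output_root() and run(cargs).
# cliwrap_dry_runner() records argv and never spawns a process.

fmt_value <- function(v) {
  if (is.logical(v)) stop("booleans are flag-only")
  if (is.numeric(v)) {
    if (is.finite(v) && v == floor(v) && abs(v) < 1e15) {
      return(sprintf("%.0f", v))
    }
    return(format(v, trim = TRUE, scientific = NA))
  }
  as.character(v)
}

join_path <- function(...) {
  paste(..., sep = "/")
}

cliwrap_strip_suffix <- function(name, suffixes) {
  best <- ""
  for (s in suffixes) {
    if (endsWith(name, s) && nchar(s) > nchar(best)) best <- s
  }
  if (nchar(best) > 0) substr(name, 1, nchar(name) - nchar(best)) else name
}

template_part <- function(value, is_file, strip) {
  s <- fmt_value(value)
  if (is_file) s <- basename(s)
  cliwrap_strip_suffix(s, strip)
}

cliwrap_dry_runner <- function() {
  self <- new.env()
  self$records <- list()
  self$last_cargs <- NULL
  self$seq <- 0L
  self$new_execution <- function(metadata) {
    self$seq <- self$seq + 1L
    seq_now <- self$seq
    ex <- new.env()
    ex$translate_input <- function(path) path
    ex$output_root <- function() {
      paste0(metadata[["uid"]], "_", seq_now)
    }
    ex$run <- function(cargs) {
      self$last_cargs <- as.character(cargs)
      self$records[[length(self$records) + 1L]] <- list(
        seq = seq_now, uid = metadata[["uid"]], cargs = as.character(cargs))
      invisible(0L)
    }
    ex
  }
  self
}

default_runner <- function() {
  cliwrap_dry_runner()
}
'''

COMPANION = DialectProfile(
    name="companion",
    file_extension=".R",
    indent="  ",
    block_end="}",
    doc_inside=False,
    doc_open="#' {first}",
    doc_line="#' {text}",
    doc_close="#'",
    reserved=frozenset(R_RESERVED),
    shim_filename="cliwrap_shim.R",
    shim_source=_R_SHIM,
    record_def="",
    templates={
        "module_header": "# Generated interface. source() cliwrap_shim.R before this file.",
        "comment": "# {text}",
        "func_def": "{name} <- function({args}) {{",
        "if": "if ({cond}) {{",
        "elif": "}} else if ({cond}) {{",
        "else": "}} else {{",
        "for": "for ({var} in {seq}) {{",
        "return": "return({value})",
        "assign": "{name} <- {value}",
        "append": "cargs <- c(cargs, {value})",
        "extend": "cargs <- c(cargs, {value})",
        "cargs_init": "cargs <- character(0)",
        "call": "{fn}({args})",
        "kwarg": "{name} = {value}",
        "dict_item": '"{key}" = {value}',
        "dict_new": "list({items})",
        "vec_lit": "c({items})",
        "not_null": "!is.null({value})",
        "is_null": "is.null({value})",
        "truthy_flag": "isTRUE({value})",
        "truthy_list": "(!is.null({value}) && length({value}) > 0)",
        "and": "{a} && {b}",
        "eq": "{a} == {b}",
        "tag_get": '{value}[["__tag"]]',
        "key_get": '{value}[["{key}"]]',
        "fmt_call": "fmt_value({value})",
        "translate_call": "execution$translate_input({value})",
        "join_list": "paste(vapply({value}, fmt_value, character(1)), collapse = {sep})",
        "concat": "paste0({items})",
        "join_path": "join_path({items})",
        "part_call": "template_part({value}, {is_file}, {strip})",
        "record_new": "list({kwargs})",
        "runner_default": "if (is.null(runner)) runner <- default_runner()",
        "new_execution": "execution <- runner$new_execution({meta})",
        "run_call": "execution$run(cargs)",
        "output_root": "execution$output_root()",
        "ternary": "(if ({cond}) {then} else {other})",
        "null": "NULL",
        "true": "TRUE",
        "false": "FALSE",
    },
)

PROFILES = {"host": HOST, "companion": COMPANION}


def get_profile(name: str) -> DialectProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown dialect profile '{name}' (have: {sorted(PROFILES)})") from None
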