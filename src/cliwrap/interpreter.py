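"""Reference semantics for IR interfaces.

This module is the single source of truth for what a descriptor *means*:

* ``check_assignment`` — every binding invariant (required params, types,
  choices, bounds, union tags, group constraints), reported as Issues
  naming parameter paths;
* ``build_cargs`` — the deterministic left-to-right argv construction that
  every generated wrapper must reproduce token for token;
* ``resolve_outputs`` — output path-template substitution with basename
  extraction and longest-suffix stripping;
* ``derives`` — a brute-force bounded grammar-membership oracle used by the
  test suite to certify that emitted argv lists are derivable from the
  descriptor's grammar (and near-miss lists are not).

Assignments are plain nested dicts/lists/scalars (JSON-shaped):

* scalar params bind scalars, flag params bind booleans;
* repeatable params bind lists (possibly empty — zero occurrences legal);
* subcommand params bind ``{param_id: value, ...}`` dicts;
* union params bind one-key ``{alternative_id: {…}}`` tagged dicts.

Argv tokens are final: nothing downstream may re-split, quote, or otherwise
shell-interpret them.
"""

from __future__ import annotations

import json
import posixpath
import re
from dataclasses import dataclass, field
from typing import Any, Mapping

from .errors import AssignmentError, Issue, OutputResolutionError
from .ir import (
    IRCarg,
    IRInterface,
    IRLiteral,
    IROutLiteral,
    IROutRef,
    IRParam,
    IRPlan,
    IRRef,
    IRValueModel,
)
from .model import ParamType

__all__ = [
    "OutputObject",
    "assignment_from_json",
    "build_cargs",
    "check_assignment",
    "derives",
    "ensure_valid_assignment",
    "format_value",
    "resolve_outputs",
]


def assignment_from_json(text: str) -> dict:
    doc = json.loads(text)
    if not isinstance(doc, dict):
        raise AssignmentError([Issue(path="", message="assignment must be a JSON object")])
    return doc


def format_value(v: Any) -> str:
    """Render one scalar as an argv token.

    Integers render without a decimal point; floats use the shortest
    round-trip decimal representation, so every dialect prints the same
    token for the same value.
    """
    if isinstance(v, bool):
        raise TypeError("booleans are flag-only and never format to a token")
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


# --------------------------------------------------------------------------
# assignment checking
# --------------------------------------------------------------------------

def _scalar_type_ok(v: Any, typ: ParamType) -> bool:
    if typ in (ParamType.STRING, ParamType.FILE):
        return isinstance(v, str)
    if typ is ParamType.INTEGER:
        return isinstance(v, int) and not isinstance(v, bool)
    if typ is ParamType.FLOAT:
        return isinstance(v, (int, float)) and not isinstance(v, bool)
    return False


def _unwrap_subcommand(irp: IRParam, v: Any) -> Any:
    """Accept the tagged one-key spelling for plain subcommands.

    A union hoisted to a subcommand keeps accepting ``{body_id: {...}}``;
    the key is unwrapped when it names the sole nested plan and is not
    itself a parameter of that plan.
    """
    assert irp.nested is not None
    (body_id, plan), = irp.nested.items()
    if (isinstance(v, dict) and set(v) == {body_id}
            and isinstance(v[body_id], dict)
            and not any(p.endswith("/" + body_id) or p == body_id
                        for p in plan.param_paths)):
        return v[body_id]
    return v


def _check_scalar(vm: IRValueModel, v: Any, path: str, issues: list[Issue]) -> None:
    if not _scalar_type_ok(v, vm.type):
        issues.append(Issue(path=path,
                            message=f"expected {vm.type.value}, got {type(v).__name__} {v!r}"))
        return
    if vm.choices is not None and v not in vm.choices:
        issues.append(Issue(path=path, message=f"value {v!r} not among choices {vm.choices}"))
    if vm.minimum is not None and v < vm.minimum:
        issues.append(Issue(path=path, message=f"value {v!r} below minimum {vm.minimum}"))
    if vm.maximum is not None and v > vm.maximum:
        issues.append(Issue(path=path, message=f"value {v!r} above maximum {vm.maximum}"))


def _check_one(ir: IRInterface, irp: IRParam, v: Any, issues: list[Issue]) -> None:
    vm = irp.value_model
    path = irp.path
    if vm.type is ParamType.FLAG:
        if not isinstance(v, bool):
            issues.append(Issue(path=path, message=f"flag expects a boolean, got {v!r}"))
        return
    if vm.type is ParamType.UNION:
        if not (isinstance(v, dict) and len(v) == 1):
            issues.append(Issue(path=path,
                                message="union value must be a one-key {alternative: {...}} object"))
            return
        (tag, sub), = v.items()
        assert irp.nested is not None
        if tag not in irp.nested:
            issues.append(Issue(path=path,
                                message=f"unknown alternative '{tag}' "
                                        f"(expected one of {sorted(irp.nested)})"))
            return
        if not isinstance(sub, dict):
            issues.append(Issue(path=path, message="alternative body must be an object"))
            return
        _check_level(ir, irp.nested[tag], sub, issues)
        return
    if vm.type is ParamType.SUBCOMMAND:
        v = _unwrap_subcommand(irp, v)
        if not isinstance(v, dict):
            issues.append(Issue(path=path, message=f"subcommand value must be an object, got {v!r}"))
            return
        (_, plan), = irp.nested.items()  # type: ignore[union-attr]
        _check_level(ir, plan, v, issues)
        return
    _check_scalar(vm, v, path, issues)


def _check_level(ir: IRInterface, plan: IRPlan, a: Mapping[str, Any],
                 issues: list[Issue]) -> None:
    known = {ir.params[p].id: p for p in plan.param_paths}
    for key in a:
        if key not in known:
            issues.append(Issue(path=key, message=f"unknown parameter '{key}'"))
    for path in plan.param_paths:
        irp = ir.params[path]
        vm = irp.value_model
        v = a.get(irp.id)
        if v is None:
            if vm.type is ParamType.FLAG or vm.optional or vm.has_default or vm.repeatable:
                continue
            issues.append(Issue(path=path, message="missing required parameter"))
            continue
        if vm.repeatable:
            if not isinstance(v, list):
                issues.append(Issue(path=path, message=f"repeatable parameter expects a list, got {v!r}"))
                continue
            for k, item in enumerate(v):
                _check_one(ir, irp, item, issues)
        else:
            _check_one(ir, irp, v, issues)


def _is_bound(vm: IRValueModel, v: Any) -> bool:
    if v is None:
        return False
    if vm.type is ParamType.FLAG:
        return v is True
    if vm.repeatable and isinstance(v, list):
        return len(v) > 0
    return True


def check_assignment(ir: IRInterface, a: Mapping[str, Any]) -> list[Issue]:
    """Return every binding violation; empty list means the assignment is runnable."""
    issues: list[Issue] = []
    if not isinstance(a, Mapping):
        return [Issue(path="", message="assignment must be an object")]
    _check_level(ir, ir.plan, a, issues)
    by_id = {ir.params[p].id: ir.params[p] for p in ir.plan.param_paths}
    for g in ir.groups:
        bound = [m for m in g.members
                 if m in by_id and _is_bound(by_id[m].value_model, a.get(m))]
        if g.mutually_exclusive and len(bound) > 1:
            issues.append(Issue(path=f"groups/{g.id}",
                                message=f"parameters {bound} are mutually exclusive"))
        if g.one_required and not bound:
            issues.append(Issue(path=f"groups/{g.id}",
                                message=f"one of {g.members} is required"))
    return sorted(issues)


def ensure_valid_assignment(ir: IRInterface, a: Mapping[str, Any]) -> None:
    issues = check_assignment(ir, a)
    if issues:
        raise AssignmentError(issues)


# --------------------------------------------------------------------------
# argv construction
# --------------------------------------------------------------------------

def _bound_value(vm: IRValueModel, a: Mapping[str, Any], pid: str) -> Any:
    v = a.get(pid)
    if v is None and vm.has_default:
        return vm.default
    return v


def _emit_scalar(vm: IRValueModel, v: Any, out: list[str]) -> None:
    if vm.repeatable:
        items = v or []
        if not items:
            return
        toks = [format_value(e) for e in items]
        if vm.flag_token:
            out.append(vm.flag_token)
        if vm.join_separator is not None:
            out.append(vm.join_separator.join(toks))
        else:
            out.extend(toks)
    else:
        if v is None:
            return
        if vm.flag_token:
            out.append(vm.flag_token)
        out.append(format_value(v))


def _emit_param(ir: IRInterface, irp: IRParam, a: Mapping[str, Any],
                out: list[str]) -> None:
    vm = irp.value_model
    v = _bound_value(vm, a, irp.id)
    if vm.type is ParamType.FLAG:
        if v is True:
            out.append(vm.flag_token or "")
        return
    if vm.type.is_nested:
        items = (v or []) if vm.repeatable else ([v] if v is not None else [])
        for item in items:
            if vm.type is ParamType.UNION:
                (tag, sub), = item.items()
                _emit_plan(ir, irp.nested[tag], sub, out)  # type: ignore[index]
            else:
                sub = _unwrap_subcommand(irp, item)
                (_, plan), = irp.nested.items()  # type: ignore[union-attr]
                _emit_plan(ir, plan, sub, out)
        return
    _emit_scalar(vm, v, out)


def _emit_plan(ir: IRInterface, plan: IRPlan, a: Mapping[str, Any],
               out: list[str]) -> None:
    for carg in plan.cargs:
        if len(carg.parts) == 1 and isinstance(carg.parts[0], IRRef):
            _emit_param(ir, ir.params[carg.parts[0].path], a, out)
            continue
        # multi-part carg: concatenate rendered scalar parts into one token;
        # any unbound optional reference suppresses the whole token
        pieces: list[str] = []
        omitted = False
        for part in carg.parts:
            if isinstance(part, IRLiteral):
                pieces.append(part.text)
            else:
                irp = ir.params[part.path]
                v = _bound_value(irp.value_model, a, irp.id)
                if v is None:
                    omitted = True
                    break
                pieces.append(format_value(v))
        if not omitted and pieces:
            out.append("".join(pieces))


def build_cargs(ir: IRInterface, a: Mapping[str, Any]) -> list[str]:
    """Build the final argv token list; deterministic, never shell-interpreted."""
    out: list[str] = []
    _emit_plan(ir, ir.plan, a, out)
    return out


# --------------------------------------------------------------------------
# output resolution
# --------------------------------------------------------------------------

@dataclass
class OutputObject:
    """Resolved output paths, relative to a designated root directory."""

    root: str = "."
    files: dict[str, str] = field(default_factory=dict)

    def path(self, legal_name: str) -> str:
        return posixpath.join(self.root, self.files[legal_name])


def _strip_suffix(name: str, suffixes: list[str]) -> str:
    best = ""
    for s in suffixes:
        if name.endswith(s) and len(s) > len(best):
            best = s
    return name[: len(name) - len(best)] if best else name


def resolve_outputs(ir: IRInterface, a: Mapping[str, Any], root: str = ".") -> OutputObject:
    """Substitute output path templates.

    File-valued references contribute their basename; the longest matching
    listed suffix is stripped before substitution.  An output whose template
    references an unbound optional parameter is omitted when the output is
    optional, otherwise resolution fails.
    """
    obj = OutputObject(root=root)
    for o in ir.outputs:
        pieces: list[str] = []
        unresolved = False
        for part in o.parts:
            if isinstance(part, IROutLiteral):
                pieces.append(part.text)
                continue
            irp = ir.params[part.path]
            v = _bound_value(irp.value_model, a, irp.id)
            if v is None:
                unresolved = True
                break
            s = format_value(v)
            if irp.value_model.type is ParamType.FILE:
                s = posixpath.basename(s)
            pieces.append(_strip_suffix(s, part.strip))
        if unresolved:
            if o.optional:
                continue
            raise OutputResolutionError(
                f"output '{o.id}' references an unbound parameter and is not optional")
        obj.files[o.legal_name] = "".join(pieces)
    return obj


# --------------------------------------------------------------------------
# grammar-membership oracle (test-only; brute force, bounded)
# --------------------------------------------------------------------------

_INT_RE = re.compile(r"[+-]?\d+$")
_FLOAT_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _token_matches(tok: str, vm: IRValueModel) -> bool:
    if vm.choices is not None:
        return any(tok == format_value(c) for c in vm.choices)
    if vm.type is ParamType.INTEGER:
        if not _INT_RE.match(tok):
            return False
        v: float = int(tok)
    elif vm.type is ParamType.FLOAT:
        if not _FLOAT_RE.match(tok):
            return False
        v = float(tok)
    else:
        return True
    if vm.minimum is not None and v < vm.minimum:
        return False
    if vm.maximum is not None and v > vm.maximum:
        return False
    return True


def _multi_regex(ir: IRInterface, carg: IRCarg) -> tuple[re.Pattern, bool]:
    pat = []
    any_optional = False
    for part in carg.parts:
        if isinstance(part, IRLiteral):
            pat.append(re.escape(part.text))
        else:
            vm = ir.params[part.path].value_model
            if vm.optional and not vm.has_default:
                any_optional = True
            if vm.type is ParamType.INTEGER:
                pat.append(r"[+-]?\d+")
            elif vm.type is ParamType.FLOAT:
                pat.append(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
            else:
                pat.append(r".*?")
    return re.compile("".join(pat) + "$"), any_optional


def _match_param(ir: IRInterface, irp: IRParam, tokens: list[str], i: int,
                 depth: int) -> set[int]:
    vm = irp.value_model
    res: set[int] = set()
    if (vm.optional and not vm.has_default) or vm.repeatable or vm.type is ParamType.FLAG:
        res.add(i)
    if vm.type is ParamType.FLAG:
        if vm.flag_token and i < len(tokens) and tokens[i] == vm.flag_token:
            res.add(i + 1)
        return res
    if vm.type.is_nested:
        if depth <= 0:
            return res
        plans = list(irp.nested.values())  # type: ignore[union-attr]

        def once(start: int) -> set[int]:
            got: set[int] = set()
            for plan in plans:
                got |= _match_plan(ir, plan, tokens, {start}, depth - 1)
            return got

        if vm.repeatable:
            reach = {i}
            frontier = {i}
            while frontier:
                new: set[int] = set()
                for f in frontier:
                    new |= once(f)
                new -= reach
                reach |= new
                frontier = new
            res |= reach
        else:
            res |= once(i)
        return res

    # scalars
    j = i
    if vm.flag_token:
        if j >= len(tokens) or tokens[j] != vm.flag_token:
            return res
        j += 1
    if vm.repeatable:
        if vm.join_separator is not None:
            if j < len(tokens):
                parts = tokens[j].split(vm.join_separator)
                if parts and all(_token_matches(p, vm) for p in parts):
                    res.add(j + 1)
        else:
            k = j
            while k < len(tokens) and _token_matches(tokens[k], vm):
                k += 1
                res.add(k)
    else:
        if j < len(tokens) and _token_matches(tokens[j], vm):
            res.add(j + 1)
    return res


def _match_plan(ir: IRInterface, plan: IRPlan, tokens: list[str],
                starts: set[int], depth: int) -> set[int]:
    current = set(starts)
    for carg in plan.cargs:
        if not current:
            return set()
        nxt: set[int] = set()
        if len(carg.parts) == 1 and isinstance(carg.parts[0], IRRef):
            irp = ir.params[carg.parts[0].path]
            for i in sorted(current):
                nxt |= _match_param(ir, irp, tokens, i, depth)
        else:
            rx, eps = _multi_regex(ir, carg)
            for i in sorted(current):
                if eps:
                    nxt.add(i)
                if i < len(tokens) and rx.match(tokens[i]):
                    nxt.add(i + 1)
        current = nxt
    return current


def derives(ir: IRInterface, tokens: list[str], depth_cap: int = 10) -> bool:
    """True iff ``tokens`` is derivable from the descriptor's grammar.

    Exhaustive bounded derivation over the carg plan: every position
    reachable after each plan step is kept, nested plans recurse up to
    ``depth_cap`` levels.  Intended as a test oracle, not a runtime check.
    """
    if depth_cap < 1:
        raise ValueError("depth_cap must be ≥ 1")
    return len(tokens) in _match_plan(ir, ir.plan, tokens, {0}, depth_cap)
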