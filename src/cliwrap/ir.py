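"""Intermediate representation: a normalized, language-agnostic interface model.

``lower`` flattens a validated descriptor into:

* a ``carg_plan`` — the ordered recipe for building argv, each entry (an
  :class:`IRCarg`) producing at most one argv token per emission, made of
  literal and parameter-reference parts;
* a flat parameter registry keyed by "/"-joined paths
  (``ops/add/value``), giving every nesting level a stable address for
  diagnostics, assignments and dependency-graph labels;
* resolved output templates with extension-strip annotations;
* mangled ``legal_name``s valid as identifiers in every shipped dialect.

Defaults are materialized in the IR so all backends agree on behavior
without re-reading the descriptor.  ``optimize`` applies the four
semantics-preserving rewrites (literal merging, empty-carg dropping,
single-alternative-union hoisting, legal-name deduplication); anything
beyond these must come with an argv-equivalence proof in the test suite.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Union

from .errors import MangleError
from .model import (
    ContainerSpec,
    GroupSpec,
    OutputSpec,
    Param,
    ParamType,
    SubCommand,
    ToolDescriptor,
    _VALUE_KEY_FIND_RE,
)
from .reserved import ALL_RESERVED


# --------------------------------------------------------------------------
# identifier mangling
# --------------------------------------------------------------------------

def mangle(raw: str, used: set[str] | None = None) -> str:
    """Turn an arbitrary descriptor name into a cross-dialect identifier.

    Lowercase; runs of non-alphanumerics collapse to "_" (stripped at the
    ends); a leading digit gets prefix "v_"; names reserved in any shipped
    dialect get suffix "_"; collisions within ``used`` get "_2", "_3", …
    The result is added to ``used`` (mutated in place).
    """
    if used is None:
        used = set()
    base = re.sub(r"[^a-z0-9]+", "_", raw.lower()).strip("_")
    if not base:
        raise MangleError(f"cannot derive an identifier from {raw!r}")
    if base[0].isdigit():
        base = "v_" + base
    if base in ALL_RESERVED:
        base = base + "_"
    name = base
    k = 2
    while name in used:
        name = f"{base}_{k}"
        k += 1
    used.add(name)
    return name


# --------------------------------------------------------------------------
# IR data types
# --------------------------------------------------------------------------

@dataclass
class IRLiteral:
    text: str


@dataclass
class IRRef:
    path: str


IRPart = Union[IRLiteral, IRRef]


@dataclass
class IRCarg:
    """One argv-token recipe.

    A single-part param reference uses the parameter's full emission
    semantics (flags, repetition, nested plans).  Multi-part cargs
    concatenate rendered scalar parts into one token; if any referenced
    optional parameter is unbound the whole carg is omitted.
    """

    parts: list[IRPart] = field(default_factory=list)


@dataclass
class IRPlan:
    """The carg recipe and local parameter order for one nesting level."""

    cargs: list[IRCarg] = field(default_factory=list)
    param_paths: list[str] = field(default_factory=list)


@dataclass
class IRValueModel:
    type: ParamType
    optional: bool = False
    repeatable: bool = False
    default: Any = None
    has_default: bool = False
    flag_token: Optional[str] = None
    join_separator: Optional[str] = None
    choices: Optional[list[Any]] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None


@dataclass
class IRParam:
    path: str          # level-qualified: "ops/add/value"
    id: str            # local id: "value"
    legal_name: str
    doc: str = ""
    value_model: IRValueModel = None  # type: ignore[assignment]
    # subcommand: single-entry dict; union: one entry per alternative
    nested: Optional[dict[str, IRPlan]] = None


@dataclass
class IROutLiteral:
    text: str


@dataclass
class IROutRef:
    path: str
    strip: list[str] = field(default_factory=list)


@dataclass
class IROutput:
    id: str
    legal_name: str
    doc: str = ""
    parts: list[Union[IROutLiteral, IROutRef]] = field(default_factory=list)
    optional: bool = False


@dataclass
class IRDoc:
    title: str = ""
    description: str = ""
    authors: list[str] = field(default_factory=list)
    url: str = ""
    tool_version: str = ""
    original_id: str = ""


@dataclass
class IRInterface:
    uid: str
    doc: IRDoc = field(default_factory=IRDoc)
    plan: IRPlan = field(default_factory=IRPlan)
    params: dict[str, IRParam] = field(default_factory=dict)
    outputs: list[IROutput] = field(default_factory=list)
    container: Optional[ContainerSpec] = None
    groups: list[GroupSpec] = field(default_factory=list)

    def level_params(self, plan: IRPlan) -> list[IRParam]:
        return [self.params[p] for p in plan.param_paths]

    def user_settable_count(self) -> int:
        """Number of user-facing value slots (all levels, unions count each alt's params)."""
        return len(self.params)


# --------------------------------------------------------------------------
# lowering
# --------------------------------------------------------------------------

def _value_model(p: Param) -> IRValueModel:
    return IRValueModel(
        type=p.type,
        optional=p.optional,
        repeatable=p.repeatable,
        default=copy.deepcopy(p.default),
        has_default=p.has_default,
        flag_token=p.flag_token,
        join_separator=p.join_separator,
        choices=copy.deepcopy(p.choices),
        minimum=p.minimum,
        maximum=p.maximum,
    )


def _lower_level(
    ir: IRInterface,
    template,
    params: list[Param],
    prefix: str,
) -> IRPlan:
    plan = IRPlan()
    used: set[str] = set()
    by_id: dict[str, str] = {}
    for p in params:
        path = f"{prefix}{p.id}"
        legal = mangle(p.id, used)
        irp = IRParam(path=path, id=p.id, legal_name=legal,
                      doc=p.doc, value_model=_value_model(p))
        if p.type.is_nested:
            irp.nested = {}
            for alt in p.alternatives:
                irp.nested[alt.id] = _lower_level(
                    ir, alt.command_template, alt.params, f"{path}/{alt.id}/")
        ir.params[path] = irp
        plan.param_paths.append(path)
        by_id[p.id] = path
    for tok in template:
        if tok.kind == "literal":
            plan.cargs.append(IRCarg([IRLiteral(tok.text)]))
        else:
            plan.cargs.append(IRCarg([IRRef(by_id[tok.text])]))
    return plan


def _lower_outputs(ir: IRInterface, d: ToolDescriptor) -> None:
    used = {"root"}
    key_to_path = {p.value_key: p.id for p in d.params}
    for o in d.outputs:
        parts: list[Union[IROutLiteral, IROutRef]] = []
        pos = 0
        for m in _VALUE_KEY_FIND_RE.finditer(o.path_template):
            if m.start() > pos:
                parts.append(IROutLiteral(o.path_template[pos:m.start()]))
            parts.append(IROutRef(path=key_to_path[m.group(0)],
                                  strip=list(o.stripped_extensions)))
            pos = m.end()
        if pos < len(o.path_template):
            parts.append(IROutLiteral(o.path_template[pos:]))
        ir.outputs.append(IROutput(
            id=o.id,
            legal_name=mangle(o.id, used),
            doc=o.doc,
            parts=parts,
            optional=o.optional,
        ))


def lower(d: ToolDescriptor) -> IRInterface:
    """Lower a validated descriptor into the IR.  Total and deterministic."""
    ir = IRInterface(
        uid=mangle(d.id or d.name),
        doc=IRDoc(
            title=d.name,
            description=d.doc,
            authors=list(d.authors),
            url=d.url,
            tool_version=d.tool_version,
            original_id=d.id,
        ),
        container=copy.deepcopy(d.container),
        groups=copy.deepcopy(d.groups),
    )
    ir.plan = _lower_level(ir, d.command_template, d.params, "")
    _lower_outputs(ir, d)
    return ir


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------

def _merge_literals(carg: IRCarg) -> IRCarg:
    parts: list[IRPart] = []
    for part in carg.parts:
        if (isinstance(part, IRLiteral) and parts
                and isinstance(parts[-1], IRLiteral)):
            parts[-1] = IRLiteral(parts[-1].text + part.text)
        else:
            parts.append(copy.deepcopy(part))
    return IRCarg(parts)


def _optimize_plan(ir: IRInterface, plan: IRPlan) -> IRPlan:
    cargs = [_merge_literals(c) for c in plan.cargs]
    cargs = [c for c in cargs if c.parts]
    return IRPlan(cargs=cargs, param_paths=list(plan.param_paths))


def optimize(ir: IRInterface) -> IRInterface:
    """Apply the four semantics-preserving rewrites; idempotent, non-mutating.

    build_cargs output is identical before and after for every assignment
    (enforced by the equivalence property suite).
    """
    out = copy.deepcopy(ir)
    out.plan = _optimize_plan(out, out.plan)
    for irp in out.params.values():
        if irp.nested is not None:
            irp.nested = {k: _optimize_plan(out, v) for k, v in irp.nested.items()}
            # hoist single-alternative unions into plain subcommands
            if irp.value_model.type is ParamType.UNION and len(irp.nested) == 1:
                irp.value_model.type = ParamType.SUBCOMMAND
    # deduplicate legal names per sibling scope (defensive: programmatic IR)
    def dedupe(plan: IRPlan) -> None:
        used: set[str] = set()
        for p in out.level_params(plan):
            if p.legal_name in used:
                p.legal_name = mangle(p.legal_name, used)
            else:
                used.add(p.legal_name)
    dedupe(out.plan)
    for irp in out.params.values():
        if irp.nested:
            for sub in irp.nested.values():
                dedupe(sub)
    return out


# --------------------------------------------------------------------------
# debug dump (non-public JSON form; see docs/methods.md)
# --------------------------------------------------------------------------

def _part_to_obj(part: IRPart) -> Any:
    if isinstance(part, IRLiteral):
        return {"lit": part.text}
    return {"ref": part.path}


def ir_to_debug_dict(ir: IRInterface) -> dict:
    def plan_obj(plan: IRPlan) -> dict:
        return {
            "cargs": [[_part_to_obj(p) for p in c.parts] for c in plan.cargs],
            "params": list(plan.param_paths),
        }

    params = {}
    for path in sorted(ir.params):
        irp = ir.params[path]
        vm = irp.value_model
        params[path] = {
            "legal_name": irp.legal_name,
            "type": vm.type.value,
            "optional": vm.optional,
            "repeatable": vm.repeatable,
            **({"default": vm.default} if vm.has_default else {}),
            **({"flag": vm.flag_token} if vm.flag_token else {}),
            **({"nested": {k: plan_obj(v) for k, v in irp.nested.items()}}
               if irp.nested else {}),
        }
    return {
        "uid": ir.uid,
        "plan": plan_obj(ir.plan),
        "params": params,
        "outputs": [
            {
                "id": o.id,
                "legal_name": o.legal_name,
                "optional": o.optional,
                "parts": [
                    {"lit": p.text} if isinstance(p, IROutLiteral)
                    else {"ref": p.path, "strip": p.strip}
                    for p in o.parts
                ],
            }
            for o in ir.outputs
        ],
    }
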