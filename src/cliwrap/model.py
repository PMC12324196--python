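"""Descriptor dialect: parse, validate and serialize tool descriptions.

The dialect is extended Boutiques JSON.  A classic flat descriptor — string
``command-line`` with ``[VALUE_KEY]`` tokens, ``inputs`` with ``type`` in
{"String", "File", "Number", "Flag"}, ``output-files`` with ``path-template``
— parses unchanged.  The extension is a single rule: an input's ``type`` may
also be an object (a nested subcommand) or an array of ≥2 objects (mutually
exclusive subcommand alternatives), and ``"list": true`` on such an input
allows the subcommand to repeat.  Those three constructions give the dialect
hierarchy, alternation and repetition while staying a regular language: a
descriptor's nesting is finite structure, never self-reference, and a depth
cap of 10 is enforced at validation time.

Key model points:

* ``command-line`` is tokenized on whitespace; a token that exactly equals a
  parameter's ``value-key`` (canonically ``[UPPER_SNAKE]``) is a placeholder,
  everything else is a literal.  Value-keys embedded inside a longer token
  are rejected — one template token becomes one argv token.
* Unknown JSON fields are preserved verbatim through parse → serialize but
  carry no semantics.
* ``groups`` (mutual exclusion / one-required) are honoured when checking
  parameter assignments; they never change argv construction.
"""

from __future__ import annotations

import json
import re
from enum import Enum
from typing import Any, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .errors import (
    CrossReferenceError,
    DescriptorParseError,
    DescriptorValidationError,
    Issue,
)

MAX_NESTING_DEPTH = 10

_VALUE_KEY_RE = re.compile(r"^\[[A-Z0-9_]+\]$")
_VALUE_KEY_FIND_RE = re.compile(r"\[[A-Z0-9_]+\]")


class ParamType(str, Enum):
    STRING = "string"
    INTEGER = "integer"
    FLOAT = "float"
    FILE = "file"
    FLAG = "flag"
    SUBCOMMAND = "subcommand"
    UNION = "union"

    @property
    def is_scalar(self) -> bool:
        return self in (ParamType.STRING, ParamType.INTEGER, ParamType.FLOAT, ParamType.FILE)

    @property
    def is_nested(self) -> bool:
        return self in (ParamType.SUBCOMMAND, ParamType.UNION)


class Token(BaseModel):
    """One command-template token: a literal string or a parameter reference."""

    model_config = ConfigDict(frozen=True)

    kind: str  # "literal" | "placeholder"
    text: str  # literal text, or the referenced param id

    @classmethod
    def literal(cls, text: str) -> "Token":
        return cls(kind="literal", text=text)

    @classmethod
    def placeholder(cls, param_id: str) -> "Token":
        return cls(kind="placeholder", text=param_id)


def default_value_key(param_id: str) -> str:
    key = re.sub(r"[^A-Za-z0-9]+", "_", param_id).upper().strip("_") or "PARAM"
    return f"[{key}]"


class SubCommand(BaseModel):
    """A nested command fragment: its own template and parameter namespace."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    id: str
    doc: str = ""
    command_template: list[Token] = Field(default_factory=list)
    params: list["Param"] = Field(default_factory=list)
    extras: dict[str, Any] = Field(default_factory=dict)


class Param(BaseModel):
    """One input slot.

    ``body`` holds the recursion: a single SubCommand for type=subcommand, a
    list of ≥2 alternatives for type=union, None otherwise.  ``flag_token``
    is the literal emitted before the value (for type=flag it *is* the whole
    emission).  ``repeatable`` params bind lists; ``join_separator`` turns
    the list into one joined argv token instead of one token per element.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    id: str
    doc: str = ""
    type: ParamType = ParamType.STRING
    value_key: str = ""
    flag_token: Optional[str] = None
    optional: bool = False
    default: Any = None
    has_default: bool = False
    repeatable: bool = False
    join_separator: Optional[str] = None
    choices: Optional[list[Any]] = None
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    body: Union[SubCommand, list[SubCommand], None] = None
    extras: dict[str, Any] = Field(default_factory=dict)

    def model_post_init(self, __context: Any) -> None:
        if not self.value_key:
            self.value_key = default_value_key(self.id)

    @property
    def alternatives(self) -> list[SubCommand]:
        if self.type is ParamType.UNION:
            assert isinstance(self.body, list)
            return self.body
        if self.type is ParamType.SUBCOMMAND:
            assert isinstance(self.body, SubCommand)
            return [self.body]
        return []


class OutputSpec(BaseModel):
    """An output file pattern: literals plus ``[VALUE_KEY]`` references.

    Referenced parameters must be file or string typed; file values are
    reduced to their basename and the longest matching entry of
    ``stripped_extensions`` is removed before substitution.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    id: str
    doc: str = ""
    path_template: str = ""
    stripped_extensions: list[str] = Field(default_factory=list)
    optional: bool = False
    extras: dict[str, Any] = Field(default_factory=dict)


class ContainerSpec(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    image: str
    tag: str = ""
    engine_hint: str = ""
    extras: dict[str, Any] = Field(default_factory=dict)


class GroupSpec(BaseModel):
    """Assignment-time constraint over top-level parameters."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    id: str
    members: list[str] = Field(default_factory=list)
    mutually_exclusive: bool = False
    one_required: bool = False
    extras: dict[str, Any] = Field(default_factory=dict)


class ToolDescriptor(BaseModel):
    """One tool's full interface description."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    name: str
    id: str = ""
    doc: str = ""
    authors: list[str] = Field(default_factory=list)
    url: str = ""
    tool_version: str = ""
    container: Optional[ContainerSpec] = None
    command_template: list[Token] = Field(default_factory=list)
    params: list[Param] = Field(default_factory=list)
    outputs: list[OutputSpec] = Field(default_factory=list)
    groups: list[GroupSpec] = Field(default_factory=list)
    extras: dict[str, Any] = Field(default_factory=dict)

    def model_post_init(self, __context: Any) -> None:
        if not self.id:
            self.id = re.sub(r"[^A-Za-z0-9]+", "_", self.name).strip("_").lower()


# --------------------------------------------------------------------------
# JSON -> model
# --------------------------------------------------------------------------

_KNOWN_TOP = {
    "name", "id", "description", "author", "url", "tool-version",
    "command-line", "container-image", "inputs", "output-files", "groups",
}
_KNOWN_INPUT = {
    "id", "name", "description", "value-key", "type", "optional", "list",
    "list-separator", "command-line-flag", "default-value", "value-choices",
    "minimum", "maximum", "integer",
}
_KNOWN_SUBCOMMAND = {"id", "name", "description", "command-line", "inputs"}
_KNOWN_OUTPUT = {
    "id", "name", "description", "path-template",
    "path-template-stripped-extensions", "optional",
}
_KNOWN_GROUP = {"id", "members", "mutually-exclusive", "one-is-required"}
_KNOWN_CONTAINER = {"type", "image", "tag"}

_SCALAR_TYPE_NAMES = {"String", "File", "Number", "Flag"}


class _Builder:
    """Structural (shape) pass: JSON document -> model objects.

    Shape problems (wrong JSON types, missing required keys) are collected as
    issues with JSON-pointer paths and raised together; semantic invariants
    are left to :func:`validate`.
    """

    def __init__(self) -> None:
        self.issues: list[Issue] = []

    def err(self, path: str, message: str) -> None:
        self.issues.append(Issue(path=path, message=message))

    def expect(self, obj: Any, typ: type, path: str, what: str) -> bool:
        if not isinstance(obj, typ):
            self.err(path, f"{what} must be {typ.__name__}, got {type(obj).__name__}")
            return False
        return True

    # -- leaf helpers ------------------------------------------------------

    def build_tokens(self, command_line: Any, params: list[Param], path: str) -> list[Token]:
        if not self.expect(command_line, str, path, "command-line"):
            return []
        by_key = {p.value_key: p.id for p in params}
        tokens: list[Token] = []
        for raw in command_line.split():
            if raw in by_key:
                tokens.append(Token.placeholder(by_key[raw]))
            else:
                tokens.append(Token.literal(raw))
        return tokens

    def build_param(self, obj: Any, path: str, depth: int) -> Optional[Param]:
        if not self.expect(obj, dict, path, "input"):
            return None
        if "id" not in obj or not isinstance(obj.get("id"), str) or not obj["id"]:
            self.err(f"{path}/id", "input requires a non-empty string id")
            return None
        extras = {k: v for k, v in obj.items() if k not in _KNOWN_INPUT}
        kwargs: dict[str, Any] = dict(
            id=obj["id"],
            doc=str(obj.get("description", "") or ""),
            value_key=obj.get("value-key", "") or "",
            flag_token=obj.get("command-line-flag"),
            optional=bool(obj.get("optional", False)),
            repeatable=bool(obj.get("list", False)),
            join_separator=obj.get("list-separator"),
            choices=obj.get("value-choices"),
            minimum=obj.get("minimum"),
            maximum=obj.get("maximum"),
            extras=extras,
        )
        if "default-value" in obj:
            kwargs["default"] = obj["default-value"]
            kwargs["has_default"] = True

        raw_type = obj.get("type", "String")
        if isinstance(raw_type, str):
            if raw_type not in _SCALAR_TYPE_NAMES:
                self.err(f"{path}/type", f"unknown type {raw_type!r}")
                return None
            if raw_type == "Number":
                kwargs["type"] = ParamType.INTEGER if obj.get("integer") else ParamType.FLOAT
            elif raw_type == "String":
                kwargs["type"] = ParamType.STRING
            elif raw_type == "File":
                kwargs["type"] = ParamType.FILE
            else:
                kwargs["type"] = ParamType.FLAG
        elif isinstance(raw_type, dict):
            kwargs["type"] = ParamType.SUBCOMMAND
            kwargs["body"] = self.build_subcommand(raw_type, f"{path}/type", depth + 1)
        elif isinstance(raw_type, list):
            kwargs["type"] = ParamType.UNION
            alts = []
            for i, alt in enumerate(raw_type):
                sub = self.build_subcommand(alt, f"{path}/type/{i}", depth + 1)
                if sub is not None:
                    alts.append(sub)
            kwargs["body"] = alts
        else:
            self.err(f"{path}/type", "type must be a string, object or array")
            return None
        return Param(**kwargs)

    def build_subcommand(self, obj: Any, path: str, depth: int) -> Optional[SubCommand]:
        if not self.expect(obj, dict, path, "subcommand"):
            return None
        if depth > MAX_NESTING_DEPTH:
            self.err(path, f"nesting exceeds the depth cap of {MAX_NESTING_DEPTH}")
            return None
        if "id" not in obj or not isinstance(obj.get("id"), str) or not obj["id"]:
            self.err(f"{path}/id", "subcommand requires a non-empty string id")
            return None
        params = self.build_params(obj.get("inputs", []), f"{path}/inputs", depth)
        tokens = self.build_tokens(obj.get("command-line", ""), params, f"{path}/command-line")
        extras = {k: v for k, v in obj.items() if k not in _KNOWN_SUBCOMMAND}
        return SubCommand(
            id=obj["id"],
            doc=str(obj.get("description", obj.get("name", "")) or ""),
            command_template=tokens,
            params=params,
            extras=extras,
        )

    def build_params(self, obj: Any, path: str, depth: int) -> list[Param]:
        if not self.expect(obj, list, path, "inputs"):
            return []
        out = []
        for i, item in enumerate(obj):
            p = self.build_param(item, f"{path}/{i}", depth)
            if p is not None:
                out.append(p)
        return out

    def build_output(self, obj: Any, path: str) -> Optional[OutputSpec]:
        if not self.expect(obj, dict, path, "output"):
            return None
        if not isinstance(obj.get("id"), str) or not obj.get("id"):
            self.err(f"{path}/id", "output requires a non-empty string id")
            return None
        extras = {k: v for k, v in obj.items() if k not in _KNOWN_OUTPUT}
        return OutputSpec(
            id=obj["id"],
            doc=str(obj.get("description", "") or ""),
            path_template=str(obj.get("path-template", "") or ""),
            stripped_extensions=list(obj.get("path-template-stripped-extensions", []) or []),
            optional=bool(obj.get("optional", False)),
            extras=extras,
        )

    def build(self, doc: Any) -> ToolDescriptor:
        if not isinstance(doc, dict):
            self.err("", "descriptor root must be a JSON object")
            raise DescriptorValidationError(sorted(self.issues))
        if not isinstance(doc.get("name"), str) or not doc.get("name"):
            self.err("/name", "descriptor requires a non-empty string name")

        container = None
        if "container-image" in doc and doc["container-image"] is not None:
            ci = doc["container-image"]
            if self.expect(ci, dict, "/container-image", "container-image"):
                container = ContainerSpec(
                    image=str(ci.get("image", "") or ""),
                    tag=str(ci.get("tag", "") or ""),
                    engine_hint=str(ci.get("type", "") or ""),
                    extras={k: v for k, v in ci.items() if k not in _KNOWN_CONTAINER},
                )

        params = self.build_params(doc.get("inputs", []), "/inputs", 1)
        tokens = self.build_tokens(doc.get("command-line", ""), params, "/command-line")

        outputs = []
        raw_outputs = doc.get("output-files", [])
        if self.expect(raw_outputs, list, "/output-files", "output-files"):
            for i, item in enumerate(raw_outputs):
                o = self.build_output(item, f"/output-files/{i}")
                if o is not None:
                    outputs.append(o)

        groups = []
        raw_groups = doc.get("groups", [])
        if self.expect(raw_groups, list, "/groups", "groups"):
            for i, item in enumerate(raw_groups):
                if not self.expect(item, dict, f"/groups/{i}", "group"):
                    continue
                groups.append(GroupSpec(
                    id=str(item.get("id", f"group_{i}")),
                    members=list(item.get("members", []) or []),
                    mutually_exclusive=bool(item.get("mutually-exclusive", False)),
                    one_required=bool(item.get("one-is-required", False)),
                    extras={k: v for k, v in item.items() if k not in _KNOWN_GROUP},
                ))

        authors = doc.get("author", [])
        if isinstance(authors, str):
            authors = [authors]
        elif not isinstance(authors, list):
            authors = []

        if self.issues:
            raise DescriptorValidationError(sorted(self.issues))

        return ToolDescriptor(
            name=doc["name"],
            id=str(doc.get("id", "") or ""),
            doc=str(doc.get("description", "") or ""),
            authors=[str(a) for a in authors],
            url=str(doc.get("url", "") or ""),
            tool_version=str(doc.get("tool-version", "") or ""),
            container=container,
            command_template=tokens,
            params=params,
            outputs=outputs,
            groups=groups,
            extras={k: v for k, v in doc.items() if k not in _KNOWN_TOP},
        )


def descriptor_from_dict(doc: dict) -> ToolDescriptor:
    """Build a descriptor from an already-decoded JSON object (no validation)."""
    return _Builder().build(doc)


def parse_descriptor(document: str) -> ToolDescriptor:
    """Parse and fully validate a descriptor document.

    Raises DescriptorParseError (bad JSON, with position),
    DescriptorValidationError (shape or invariant violations, with
    JSON-pointer paths) or CrossReferenceError (dangling/unreferenced
    placeholder, naming the parameter).
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise DescriptorParseError(exc.msg, exc.lineno, exc.colno) from exc
    d = descriptor_from_dict(doc)
    issues = [i for i in validate(d) if i.severity == "error"]
    if issues:
        for needle in ("never referenced", "dangling"):
            for issue in issues:
                if needle not in issue.message:
                    continue
                m = re.search(r"(?:placeholder|parameter) '([^']+)'", issue.message)
                if m:
                    raise CrossReferenceError(m.group(1), issues)
        raise DescriptorValidationError(issues)
    return d


# --------------------------------------------------------------------------
# validate
# --------------------------------------------------------------------------

def _value_matches_type(value: Any, typ: ParamType) -> bool:
    if typ in (ParamType.STRING, ParamType.FILE):
        return isinstance(value, str)
    if typ is ParamType.INTEGER:
        return isinstance(value, int) and not isinstance(value, bool)
    if typ is ParamType.FLOAT:
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if typ is ParamType.FLAG:
        return isinstance(value, bool)
    return False


def _validate_level(
    template: list[Token],
    params: list[Param],
    ptr: str,
    depth: int,
    issues: list[Issue],
    inputs_key: str = "inputs",
) -> None:
    if depth > MAX_NESTING_DEPTH:
        issues.append(Issue(path=ptr, message=f"nesting exceeds the depth cap of {MAX_NESTING_DEPTH}"))
        return

    by_id: dict[str, Param] = {}
    for i, p in enumerate(params):
        if p.id in by_id:
            issues.append(Issue(path=f"{ptr}/{inputs_key}/{i}/id",
                                message=f"duplicate parameter id '{p.id}' at this level"))
        else:
            by_id[p.id] = p

    # template cross-references
    cl_ptr = f"{ptr}/command-line"
    seen_placeholder = False
    literal_before = False
    referenced: dict[str, int] = {}
    for tok in template:
        if tok.kind == "literal":
            if not tok.text:
                issues.append(Issue(path=cl_ptr, message="literal token must be non-empty"))
            if not seen_placeholder:
                literal_before = True
            if _VALUE_KEY_FIND_RE.search(tok.text):
                key = _VALUE_KEY_FIND_RE.search(tok.text).group(0)
                known = {p.value_key for p in params}
                if key in known:
                    issues.append(Issue(
                        path=cl_ptr,
                        message=f"value-key {key} embedded inside token {tok.text!r}; "
                                "value-keys must stand alone as whole tokens"))
                elif _VALUE_KEY_RE.match(tok.text):
                    issues.append(Issue(
                        path=cl_ptr,
                        message=f"dangling placeholder '{tok.text}' matches no parameter value-key"))
        else:
            seen_placeholder = True
            referenced[tok.text] = referenced.get(tok.text, 0) + 1
    if template and not literal_before:
        issues.append(Issue(path=cl_ptr,
                            message="at least one literal token (the executable) must precede placeholders"))
    if not template:
        issues.append(Issue(path=cl_ptr, message="command-line must contain at least one token"))
    for pid, n in referenced.items():
        if n > 1:
            issues.append(Issue(path=cl_ptr, message=f"placeholder '{pid}' referenced {n} times"))
    for i, p in enumerate(params):
        if p.id not in referenced:
            issues.append(Issue(path=f"{ptr}/{inputs_key}/{i}",
                                message=f"parameter '{p.id}' is never referenced by the command template"))

    # per-param invariants
    for i, p in enumerate(params):
        pp = f"{ptr}/{inputs_key}/{i}"
        if p.value_key and not _VALUE_KEY_RE.match(p.value_key):
            issues.append(Issue(path=f"{pp}/value-key",
                                message=f"value-key {p.value_key!r} must look like [UPPER_SNAKE]"))
        if p.choices is not None and p.type not in (ParamType.STRING, ParamType.INTEGER, ParamType.FLOAT):
            issues.append(Issue(path=f"{pp}/value-choices",
                                message="value-choices allowed only on string/integer/float parameters"))
        if (p.minimum is not None or p.maximum is not None) and p.type not in (ParamType.INTEGER, ParamType.FLOAT):
            issues.append(Issue(path=f"{pp}/minimum",
                                message="minimum/maximum allowed only on integer/float parameters"))
        if p.minimum is not None and p.maximum is not None and p.minimum > p.maximum:
            issues.append(Issue(path=f"{pp}/minimum",
                                message=f"minimum ({p.minimum}) exceeds maximum ({p.maximum})"))
        if p.join_separator is not None and not p.repeatable:
            issues.append(Issue(path=f"{pp}/list-separator",
                                message="list-separator requires \"list\": true"))
        if p.join_separator is not None and not p.type.is_scalar:
            issues.append(Issue(path=f"{pp}/list-separator",
                                message="list-separator applies only to scalar-typed lists"))
        if p.repeatable and not p.optional:
            issues.append(Issue(path=f"{pp}/optional",
                                message="repeatable parameters must be optional (zero occurrences are legal)"))
        if p.type is ParamType.FLAG:
            if not p.flag_token:
                issues.append(Issue(path=f"{pp}/command-line-flag",
                                    message="flag parameters require a command-line-flag token"))
            if p.has_default and not isinstance(p.default, bool):
                issues.append(Issue(path=f"{pp}/default-value",
                                    message="flag default must be boolean"))
        if p.flag_token is not None and not p.flag_token:
            issues.append(Issue(path=f"{pp}/command-line-flag",
                                message="command-line-flag must be non-empty"))
        if p.type.is_nested:
            if p.type is ParamType.UNION:
                alts = p.body if isinstance(p.body, list) else []
                if len(alts) < 2:
                    issues.append(Issue(path=f"{pp}/type",
                                        message="union requires ≥2 alternatives"))
                ids = [a.id for a in alts]
                if len(set(ids)) != len(ids):
                    issues.append(Issue(path=f"{pp}/type",
                                        message="union alternative ids must be distinct"))
                for j, alt in enumerate(alts):
                    _validate_level(alt.command_template, alt.params,
                                    f"{pp}/type/{j}", depth + 1, issues)
            else:
                if not isinstance(p.body, SubCommand):
                    issues.append(Issue(path=f"{pp}/type", message="subcommand body missing"))
                else:
                    _validate_level(p.body.command_template, p.body.params,
                                    f"{pp}/type", depth + 1, issues)
            if p.has_default and p.default is not None:
                issues.append(Issue(path=f"{pp}/default-value",
                                    message="subcommand/union parameters cannot carry defaults"))
        if p.has_default and p.default is not None and p.type.is_scalar:
            if p.repeatable:
                ok = isinstance(p.default, list) and all(
                    _value_matches_type(v, p.type) for v in p.default)
            else:
                ok = _value_matches_type(p.default, p.type)
            if not ok:
                issues.append(Issue(path=f"{pp}/default-value",
                                    message=f"default does not match type {p.type.value}"))
            else:
                values = p.default if isinstance(p.default, list) else [p.default]
                for v in values:
                    if p.choices is not None and v not in p.choices:
                        issues.append(Issue(path=f"{pp}/default-value",
                                            message=f"default {v!r} not among value-choices"))
                    if p.minimum is not None and isinstance(v, (int, float)) and v < p.minimum:
                        issues.append(Issue(path=f"{pp}/default-value",
                                            message=f"default {v!r} below minimum {p.minimum}"))
                    if p.maximum is not None and isinstance(v, (int, float)) and v > p.maximum:
                        issues.append(Issue(path=f"{pp}/default-value",
                                            message=f"default {v!r} above maximum {p.maximum}"))


def validate(d: ToolDescriptor) -> list[Issue]:
    """Return every invariant violation as an ordered, deterministic list."""
    issues: list[Issue] = []
    if not d.name:
        issues.append(Issue(path="/name", message="name must be non-empty"))
    _validate_level(d.command_template, d.params, "", 1, issues)

    if d.container is not None and not d.container.image:
        issues.append(Issue(path="/container-image/image", message="container image must be non-empty"))

    top_ids = {p.id: p for p in d.params}
    seen_out: set[str] = set()
    for i, o in enumerate(d.outputs):
        op = f"/output-files/{i}"
        if o.id in seen_out:
            issues.append(Issue(path=f"{op}/id", message=f"duplicate output id '{o.id}'"))
        seen_out.add(o.id)
        if not o.path_template:
            issues.append(Issue(path=f"{op}/path-template", message="path-template must be non-empty"))
        for ext in o.stripped_extensions:
            if not ext.startswith("."):
                issues.append(Issue(path=f"{op}/path-template-stripped-extensions",
                                    message=f"extension {ext!r} must begin with '.'"))
        by_key = {p.value_key: p for p in d.params}
        for key in _VALUE_KEY_FIND_RE.findall(o.path_template):
            p = by_key.get(key)
            if p is None:
                issues.append(Issue(path=f"{op}/path-template",
                                    message=f"path-template references unknown value-key {key}"))
            elif p.type not in (ParamType.FILE, ParamType.STRING):
                issues.append(Issue(path=f"{op}/path-template",
                                    message=f"path-template may only reference file/string parameters, "
                                            f"'{p.id}' is {p.type.value}"))

    seen_groups: set[str] = set()
    for i, g in enumerate(d.groups):
        gp = f"/groups/{i}"
        if g.id in seen_groups:
            issues.append(Issue(path=f"{gp}/id", message=f"duplicate group id '{g.id}'"))
        seen_groups.add(g.id)
        for m in g.members:
            if m not in top_ids:
                issues.append(Issue(path=f"{gp}/members",
                                    message=f"group member '{m}' is not a top-level parameter"))
    return sorted(issues)


# --------------------------------------------------------------------------
# model -> JSON
# --------------------------------------------------------------------------

def _template_to_string(template: list[Token], params: list[Param]) -> str:
    key_of = {p.id: p.value_key for p in params}
    parts = []
    for tok in template:
        parts.append(tok.text if tok.kind == "literal" else key_of.get(tok.text, tok.text))
    return " ".join(parts)


def _param_to_dict(p: Param) -> dict:
    out: dict[str, Any] = {"id": p.id}
    if p.doc:
        out["description"] = p.doc
    if p.type is ParamType.SUBCOMMAND:
        out["type"] = _subcommand_to_dict(p.body)  # type: ignore[arg-type]
    elif p.type is ParamType.UNION:
        out["type"] = [_subcommand_to_dict(a) for a in p.body]  # type: ignore[union-attr]
    elif p.type is ParamType.STRING:
        out["type"] = "String"
    elif p.type is ParamType.FILE:
        out["type"] = "File"
    elif p.type is ParamType.FLAG:
        out["type"] = "Flag"
    else:
        out["type"] = "Number"
        if p.type is ParamType.INTEGER:
            out["integer"] = True
    out["value-key"] = p.value_key
    if p.flag_token is not None:
        out["command-line-flag"] = p.flag_token
    if p.optional:
        out["optional"] = True
    if p.repeatable:
        out["list"] = True
    if p.join_separator is not None:
        out["list-separator"] = p.join_separator
    if p.has_default:
        out["default-value"] = p.default
    if p.choices is not None:
        out["value-choices"] = p.choices
    if p.minimum is not None:
        out["minimum"] = p.minimum
    if p.maximum is not None:
        out["maximum"] = p.maximum
    for k in sorted(p.extras):
        out[k] = p.extras[k]
    return out


def _subcommand_to_dict(s: SubCommand) -> dict:
    out: dict[str, Any] = {"id": s.id}
    if s.doc:
        out["description"] = s.doc
    out["command-line"] = _template_to_string(s.command_template, s.params)
    out["inputs"] = [_param_to_dict(p) for p in s.params]
    for k in sorted(s.extras):
        out[k] = s.extras[k]
    return out


def _output_to_dict(o: OutputSpec) -> dict:
    out: dict[str, Any] = {"id": o.id}
    if o.doc:
        out["description"] = o.doc
    out["path-template"] = o.path_template
    if o.stripped_extensions:
        out["path-template-stripped-extensions"] = o.stripped_extensions
    if o.optional:
        out["optional"] = True
    for k in sorted(o.extras):
        out[k] = o.extras[k]
    return out


def descriptor_to_dict(d: ToolDescriptor) -> dict:
    """Canonical dict form: fixed key order, extras appended sorted."""
    out: dict[str, Any] = {"name": d.name, "id": d.id}
    if d.doc:
        out["description"] = d.doc
    if d.authors:
        out["author"] = d.authors if len(d.authors) > 1 else d.authors[0]
    if d.url:
        out["url"] = d.url
    if d.tool_version:
        out["tool-version"] = d.tool_version
    out["command-line"] = _template_to_string(d.command_template, d.params)
    if d.container is not None:
        ci: dict[str, Any] = {}
        if d.container.engine_hint:
            ci["type"] = d.container.engine_hint
        ci["image"] = d.container.image
        if d.container.tag:
            ci["tag"] = d.container.tag
        for k in sorted(d.container.extras):
            ci[k] = d.container.extras[k]
        out["container-image"] = ci
    out["inputs"] = [_param_to_dict(p) for p in d.params]
    out["output-files"] = [_output_to_dict(o) for o in d.outputs]
    if d.groups:
        out["groups"] = [
            {
                "id": g.id,
                "members": g.members,
                **({"mutually-exclusive": True} if g.mutually_exclusive else {}),
                **({"one-is-required": True} if g.one_required else {}),
                **{k: g.extras[k] for k in sorted(g.extras)},
            }
            for g in d.groups
        ]
    for k in sorted(d.extras):
        out[k] = d.extras[k]
    return out


def serialize_descriptor(d: ToolDescriptor) -> str:
    """Serialize to canonical JSON text; stable across runs."""
    return json.dumps(descriptor_to_dict(d), indent=2, ensure_ascii=False) + "\n"
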