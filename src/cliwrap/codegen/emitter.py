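"""Backend: compile an IRInterface into wrapper source for a dialect profile.

The emitted wrapper exposes one callable per tool taking named parameters
(required first), union alternatives as one constructor function each
returning a tagged record, and a named-record result holding resolved
output paths.  The wrapper builds a token *list* — never a shell string —
and hands it to whatever runner it is given; the default is the shim's
dry runner.  Generation is deterministic: the same (IR, profile) pair
yields a byte-identical source tree.
"""

from __future__ import annotations

import json
from typing import Any, Mapping

from ..errors import CodegenError
from ..ir import (
    IRCarg,
    IRInterface,
    IRLiteral,
    IROutLiteral,
    IROutRef,
    IRParam,
    IRPlan,
    IRRef,
)
from ..model import ParamType
from .profiles import REQUIRED_TEMPLATES, DialectProfile

SourceTree = dict[str, str]


class _Writer:
    def __init__(self, profile: DialectProfile):
        self.p = profile
        self.lines: list[str] = []
        self.level = 0

    def t(self, tpl: str, **kw: Any) -> str:
        return self.p.templates[tpl].format(**kw)

    def line(self, text: str = "") -> None:
        if text:
            self.lines.append(self.p.indent * self.level + text)
        else:
            self.lines.append("")

    def stmt(self, tpl: str, **kw: Any) -> None:
        self.line(self.t(tpl, **kw))

    def open(self, tpl: str, **kw: Any) -> None:
        self.line(self.t(tpl, **kw))
        self.level += 1

    def chain(self, tpl: str, **kw: Any) -> None:
        """elif/else within an open block: re-emit header at parent level."""
        self.level -= 1
        self.line(self.t(tpl, **kw))
        self.level += 1

    def close(self) -> None:
        self.level -= 1
        if self.p.block_end:
            self.line(self.p.block_end)

    def text(self) -> str:
        return "\n".join(self.lines).rstrip() + "\n"


def _str_lit(s: str) -> str:
    # json string literals are valid in both shipped dialects
    return json.dumps(s, ensure_ascii=False)


def _num_lit(v: Any) -> str:
    if isinstance(v, bool):
        raise CodegenError("boolean is not a number literal")
    return repr(v) if isinstance(v, float) else str(v)


def _value_lit(w: _Writer, v: Any) -> str:
    if v is None:
        return w.t("null")
    if isinstance(v, bool):
        return w.t("true") if v else w.t("false")
    if isinstance(v, str):
        return _str_lit(v)
    if isinstance(v, (int, float)):
        return _num_lit(v)
    if isinstance(v, list):
        return w.t("vec_lit", items=", ".join(_value_lit(w, e) for e in v))
    raise CodegenError(f"cannot emit literal for {v!r}")


def _needs_guard(irp: IRParam) -> bool:
    vm = irp.value_model
    return (vm.optional and not vm.has_default) or (vm.has_default and vm.default is None)


class _ToolEmitter:
    def __init__(self, ir: IRInterface, profile: DialectProfile):
        self.ir = ir
        self.p = profile
        self.w = _Writer(profile)
        self._tmp = 0

    # -- naming ------------------------------------------------------------

    def fn_name(self, path_legals: list[str], suffix: str = "") -> str:
        return "_".join([self.ir.uid] + path_legals + ([suffix] if suffix else []))

    def helper_name(self, path_legals: list[str]) -> str:
        # trailing underscore: legal in both dialects, unreachable by mangle()
        return "_".join([self.ir.uid] + path_legals) + "_cargs_"

    def legal_chain(self, path: str) -> list[str]:
        """Legal names for every path segment (param and alternative ids)."""
        segs = path.split("/")
        out: list[str] = []
        # walk: param, alt, param, alt, ... — params are in the registry
        acc = ""
        for k, seg in enumerate(segs):
            acc = seg if not acc else f"{acc}/{seg}"
            irp = self.ir.params.get(acc)
            if irp is not None:
                out.append(irp.legal_name)
            else:
                # alternative id segment: mangle-like but stable (ids are
                # already identifier-shaped in practice)
                out.append(seg)
        return out

    def tmp(self, stem: str) -> str:
        self._tmp += 1
        return f"{stem}{self._tmp}_"

    # -- documentation -----------------------------------------------------

    def doc_block(self, title: str, body_lines: list[str]) -> list[str]:
        p = self.p
        lines = [p.doc_open.format(first=title)]
        for t in body_lines:
            lines.append(p.doc_line.format(text=t).rstrip())
        lines.append(p.doc_close)
        return lines

    def param_doc(self, irp: IRParam) -> str:
        vm = irp.value_model
        bits = [vm.type.value]
        if vm.repeatable:
            bits.append("repeatable")
        if vm.optional:
            bits.append("optional")
        if vm.choices is not None:
            bits.append("choices: " + ", ".join(str(c) for c in vm.choices))
        if vm.minimum is not None:
            bits.append(f"min {vm.minimum}")
        if vm.maximum is not None:
            bits.append(f"max {vm.maximum}")
        if vm.has_default:
            bits.append(f"default {vm.default!r}")
        doc = irp.doc.replace('"""', "'''").replace("\n", " ") or "no documentation"
        return f"{irp.legal_name}: {doc} ({'; '.join(bits)})"

    # -- signatures ----------------------------------------------------------

    def signature(self, params: list[IRParam], with_runner: bool) -> str:
        w = self.w
        required, defaulted = [], []
        for irp in params:
            vm = irp.value_model
            if vm.type is ParamType.FLAG:
                dflt = vm.default if vm.has_default else False
                defaulted.append(w.t("kwarg", name=irp.legal_name,
                                     value=_value_lit(w, bool(dflt))))
            elif vm.repeatable or vm.optional or vm.has_default:
                if vm.has_default and not vm.repeatable and vm.default is not None:
                    defaulted.append(w.t("kwarg", name=irp.legal_name,
                                         value=_value_lit(w, vm.default)))
                else:
                    defaulted.append(w.t("kwarg", name=irp.legal_name,
                                         value=w.t("null")))
            else:
                required.append(irp.legal_name)
        parts = required + defaulted
        if with_runner:
            parts.append(w.t("kwarg", name="runner", value=w.t("null")))
        return ", ".join(parts)

    # -- expressions ---------------------------------------------------------

    def scalar_token(self, irp: IRParam, var: str) -> str:
        if irp.value_model.type is ParamType.FILE:
            return self.w.t("translate_call", value=var)
        return self.w.t("fmt_call", value=var)

    # -- cargs emission ------------------------------------------------------

    def emit_scalar(self, irp: IRParam, var: str) -> None:
        w = self.w
        vm = irp.value_model
        if vm.repeatable:
            w.open("if", cond=w.t("truthy_list", value=var))
            if vm.flag_token:
                w.stmt("append", value=_str_lit(vm.flag_token))
            if vm.join_separator is not None:
                w.stmt("append", value=w.t("join_list", sep=_str_lit(vm.join_separator), value=var))
            else:
                it = self.tmp("e")
                w.open("for", var=it, seq=var)
                w.stmt("append", value=self.scalar_token(irp, it))
                w.close()
            w.close()
            return
        guarded = _needs_guard(irp)
        if guarded:
            w.open("if", cond=w.t("not_null", value=var))
        if vm.flag_token:
            w.stmt("append", value=_str_lit(vm.flag_token))
        w.stmt("append", value=self.scalar_token(irp, var))
        if guarded:
            w.close()

    def emit_param(self, irp: IRParam, var: str) -> None:
        w = self.w
        vm = irp.value_model
        if vm.type is ParamType.FLAG:
            w.open("if", cond=w.t("truthy_flag", value=var))
            w.stmt("append", value=_str_lit(vm.flag_token or ""))
            w.close()
            return
        if vm.type.is_nested:
            helper = self.helper_name(self.legal_chain(irp.path))
            call = w.t("call", fn=helper, args=f"{var}, execution")
            if vm.repeatable:
                w.open("if", cond=w.t("truthy_list", value=var))
                it = self.tmp("it")
                w.open("for", var=it, seq=var)
                w.stmt("extend", value=w.t("call", fn=helper, args=f"{it}, execution"))
                w.close()
                w.close()
            elif _needs_guard(irp):
                w.open("if", cond=w.t("not_null", value=var))
                w.stmt("extend", value=call)
                w.close()
            else:
                w.stmt("extend", value=call)
            return
        self.emit_scalar(irp, var)

    def emit_plan(self, plan: IRPlan, var_of: Mapping[str, str]) -> None:
        """Emit append/extend statements for one plan; var_of maps path->local var."""
        w = self.w
        for carg in plan.cargs:
            if len(carg.parts) == 1 and isinstance(carg.parts[0], IRLiteral):
                w.stmt("append", value=_str_lit(carg.parts[0].text))
            elif len(carg.parts) == 1 and isinstance(carg.parts[0], IRRef):
                irp = self.ir.params[carg.parts[0].path]
                self.emit_param(irp, var_of[irp.path])
            else:
                self.emit_multipart(carg, var_of)

    def emit_multipart(self, carg: IRCarg, var_of: Mapping[str, str]) -> None:
        w = self.w
        guards, items = [], []
        for part in carg.parts:
            if isinstance(part, IRLiteral):
                items.append(_str_lit(part.text))
            else:
                irp = self.ir.params[part.path]
                if irp.value_model.type.is_nested or irp.value_model.repeatable:
                    raise CodegenError(
                        f"multi-part carg cannot embed nested/repeatable parameter '{irp.path}'")
                var = var_of[irp.path]
                if _needs_guard(irp):
                    guards.append(w.t("not_null", value=var))
                items.append(w.t("fmt_call", value=var))
        expr = w.t("concat", items=", ".join(items))
        if guards:
            cond = guards[0]
            for g in guards[1:]:
                cond = w.t("and", a=cond, b=g)
            w.open("if", cond=cond)
            w.stmt("append", value=expr)
            w.close()
        else:
            w.stmt("append", value=expr)

    # -- nested helpers and constructors --------------------------------------

    def level_locals(self, plan: IRPlan, source_var: str) -> dict[str, str]:
        """Bind each level param to a local read from an item record."""
        var_of = {}
        for path in plan.param_paths:
            irp = self.ir.params[path]
            vm = irp.value_model
            local = f"v_{irp.legal_name}_"
            self.w.stmt("assign", name=local,
                        value=self.w.t("key_get", value=source_var, key=irp.legal_name))
            if vm.has_default and vm.default is not None:
                self.w.open("if", cond=self.w.t("is_null", value=local))
                self.w.stmt("assign", name=local, value=_value_lit(self.w, vm.default))
                self.w.close()
            var_of[path] = local
        return var_of

    def emit_helpers(self, plan: IRPlan) -> None:
        """Depth-first: one cargs helper per nested param, dispatching unions."""
        for path in plan.param_paths:
            irp = self.ir.params[path]
            if irp.nested is None:
                continue
            for sub in irp.nested.values():
                self.emit_helpers(sub)
            w = self.w
            name = self.helper_name(self.legal_chain(irp.path))
            if not self.p.doc_inside:
                for ln in self.doc_block(f"Build argv fragment for {irp.path}.", []):
                    w.line(ln)
            w.open("func_def", name=name, args="item, execution")
            if self.p.doc_inside:
                for ln in self.doc_block(f"Build argv fragment for {irp.path}.", []):
                    w.line(ln)
            w.stmt("cargs_init")
            if irp.value_model.type is ParamType.UNION:
                w.stmt("assign", name="tag_", value=w.t("tag_get", value="item"))
                first = True
                for alt_id, sub in irp.nested.items():
                    cond = w.t("eq", a="tag_", b=_str_lit(alt_id))
                    if first:
                        w.open("if", cond=cond)
                        first = False
                    else:
                        w.chain("elif", cond=cond)
                    var_of = self.level_locals(sub, "item")
                    self.emit_plan(sub, var_of)
                w.close()
            else:
                (_, sub), = irp.nested.items()
                var_of = self.level_locals(sub, "item")
                self.emit_plan(sub, var_of)
            w.stmt("return", value="cargs")
            w.close()
            w.line()
            w.line()

    def emit_constructors(self, plan: IRPlan) -> None:
        """Typed constructors: one per union alternative, one per subcommand."""
        for path in plan.param_paths:
            irp = self.ir.params[path]
            if irp.nested is None:
                continue
            chain = self.legal_chain(irp.path)
            for alt_id, sub in irp.nested.items():
                self.emit_constructors(sub)
                params = [self.ir.params[p] for p in sub.param_paths]
                is_union = irp.value_model.type is ParamType.UNION
                name = self.fn_name(chain + ([alt_id] if is_union else []))
                title = (f"Construct the '{alt_id}' alternative for {irp.path}."
                         if is_union else f"Construct the {irp.path} subcommand value.")
                doc = self.doc_block(title, [self.param_doc(p) for p in params])
                if not self.p.doc_inside:
                    for ln in doc:
                        self.w.line(ln)
                self.w.open("func_def", name=name, args=self.signature(params, with_runner=False))
                if self.p.doc_inside:
                    for ln in doc:
                        self.w.line(ln)
                items = []
                if is_union:
                    items.append(self.w.t("dict_item", key="__tag", value=_str_lit(alt_id)))
                for p in params:
                    items.append(self.w.t("dict_item", key=p.legal_name, value=p.legal_name))
                self.w.stmt("return", value=self.w.t("dict_new", items=", ".join(items)))
                self.w.close()
                self.w.line()
                self.w.line()

    # -- outputs ---------------------------------------------------------------

    def output_expr(self, out, var_of: Mapping[str, str]) -> tuple[str, list[str]]:
        w = self.w
        items, guards = [], []
        for part in out.parts:
            if isinstance(part, IROutLiteral):
                items.append(_str_lit(part.text))
            else:
                irp = self.ir.params[part.path]
                var = var_of[irp.path]
                if _needs_guard(irp):
                    guards.append(w.t("not_null", value=var))
                is_file = irp.value_model.type is ParamType.FILE
                items.append(w.t(
                    "part_call", value=var,
                    is_file=w.t("true") if is_file else w.t("false"),
                    strip=w.t("vec_lit", items=", ".join(_str_lit(s) for s in part.strip))))
        rel = items[0] if len(items) == 1 else w.t("concat", items=", ".join(items))
        return w.t("join_path", items=f"root_, {rel}"), guards

    # -- the tool function ------------------------------------------------------

    def emit_tool_function(self) -> None:
        ir, w = self.ir, self.w
        params = ir.level_params(ir.plan)
        rec = "".join(s.capitalize() for s in ir.uid.split("_")) + "Outputs"

        doc_lines = [ir.doc.description.replace("\n", " ")] if ir.doc.description else []
        if doc_lines:
            doc_lines.append("")
        doc_lines += [self.param_doc(p) for p in params]
        doc_lines.append("runner: execution adapter; defaults to the dry runner")
        outs = ", ".join(o.legal_name for o in ir.outputs) or "root only"
        doc_lines.append(f"Returns a record of resolved output paths ({outs}).")
        doc = self.doc_block(f"{ir.doc.title} ({ir.uid}).", doc_lines)

        if self.p.record_def:
            fields = ", ".join([_str_lit("root")] + [_str_lit(o.legal_name) for o in ir.outputs])
            w.line(self.p.record_def.format(rec=rec, fields=fields))
            w.line()
            w.line()
        if not self.p.doc_inside:
            for ln in doc:
                w.line(ln)
        w.open("func_def", name=ir.uid, args=self.signature(params, with_runner=True))
        if self.p.doc_inside:
            for ln in doc:
                w.line(ln)
        w.stmt("runner_default")
        w.stmt("new_execution", meta=f"{ir.uid.upper()}_METADATA")
        # materialize non-null repeatable defaults
        for irp in params:
            vm = irp.value_model
            if vm.repeatable and vm.has_default and vm.default:
                w.open("if", cond=w.t("is_null", value=irp.legal_name))
                w.stmt("assign", name=irp.legal_name, value=_value_lit(w, vm.default))
                w.close()
        w.stmt("cargs_init")
        var_of = {p.path: p.legal_name for p in params}
        self.emit_plan(ir.plan, var_of)

        w.stmt("assign", name="root_", value=w.t("output_root"))
        kwargs = [w.t("kwarg", name="root", value="root_")]
        for out in ir.outputs:
            expr, guards = self.output_expr(out, var_of)
            if guards:
                cond = guards[0]
                for g in guards[1:]:
                    cond = w.t("and", a=cond, b=g)
                expr = w.t("ternary", cond=cond, then=expr, other=w.t("null"))
            kwargs.append(w.t("kwarg", name=out.legal_name, value=expr))
        w.stmt("assign", name="ret_",
               value=w.t("record_new", rec=rec, kwargs=", ".join(kwargs)))
        w.stmt("run_call")
        w.stmt("return", value="ret_")
        w.close()

    # -- whole module -----------------------------------------------------------

    def emit_module(self) -> str:
        ir, w = self.ir, self.w
        w.stmt("comment", text=f"{ir.doc.title} — generated wrapper, do not edit.")
        if ir.doc.url:
            w.stmt("comment", text=f"Upstream: {ir.doc.url}")
        w.line()
        for ln in self.p.templates["module_header"].split("\n"):
            w.line(ln)
        w.line()
        w.line()
        container = None
        if ir.container is not None:
            container = ir.container.image + (f":{ir.container.tag}" if ir.container.tag else "")
        meta_items = [
            w.t("dict_item", key="uid", value=_str_lit(ir.uid)),
            w.t("dict_item", key="name", value=_str_lit(ir.doc.title)),
            w.t("dict_item", key="container_image",
                value=_str_lit(container) if container else w.t("null")),
        ]
        w.stmt("assign", name=f"{ir.uid.upper()}_METADATA",
               value=w.t("dict_new", items=", ".join(meta_items)))
        w.line()
        w.line()
        self.emit_constructors(ir.plan)
        self.emit_helpers(ir.plan)
        self.emit_tool_function()
        return w.text()


def generate(ir: IRInterface, profile: DialectProfile) -> SourceTree:
    """Compile one IR interface into a source tree for ``profile``.

    The tree maps relative file paths to text: one wrapper module per tool
    plus the shared runtime shim.  Raises CodegenError naming the first
    missing syntax template.
    """
    for key in REQUIRED_TEMPLATES:
        if key not in profile.templates:
            raise CodegenError(f"profile '{profile.name}' is missing template '{key}'")
    code = _ToolEmitter(ir, profile).emit_module()
    return {
        f"{ir.uid}{profile.file_extension}": code,
        profile.shim_filename: profile.shim_source,
    }
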