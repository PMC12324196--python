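"""Backend that emits descriptor JSON from the IR (round-trip conversion)."""

from __future__ import annotations

from ..errors import CodegenError
from ..ir import (
    IRInterface,
    IRLiteral,
    IROutLiteral,
    IROutRef,
    IRParam,
    IRPlan,
    IRRef,
)
from ..model import (
    OutputSpec,
    Param,
    ParamType,
    SubCommand,
    Token,
    ToolDescriptor,
    default_value_key,
    serialize_descriptor,
)


def _param_from_ir(ir: IRInterface, irp: IRParam) -> Param:
    vm = irp.value_model
    body = None
    if irp.nested is not None:
        subs = [_subcommand_from_ir(ir, alt_id, plan)
                for alt_id, plan in irp.nested.items()]
        body = subs if vm.type is ParamType.UNION else subs[0]
    return Param(
        id=irp.id,
        doc=irp.doc,
        type=vm.type,
        value_key=default_value_key(irp.id),
        flag_token=vm.flag_token,
        optional=vm.optional,
        default=vm.default,
        has_default=vm.has_default,
        repeatable=vm.repeatable,
        join_separator=vm.join_separator,
        choices=vm.choices,
        minimum=vm.minimum,
        maximum=vm.maximum,
        body=body,
    )


def _template_from_plan(ir: IRInterface, plan: IRPlan) -> list[Token]:
    tokens: list[Token] = []
    for carg in plan.cargs:
        if len(carg.parts) == 1 and isinstance(carg.parts[0], IRLiteral):
            tokens.append(Token.literal(carg.parts[0].text))
        elif len(carg.parts) == 1 and isinstance(carg.parts[0], IRRef):
            tokens.append(Token.placeholder(ir.params[carg.parts[0].path].id))
        else:
            raise CodegenError(
                "multi-part cargs cannot be expressed in the descriptor dialect "
                "(value-keys must stand alone as whole tokens)")
    return tokens


def _subcommand_from_ir(ir: IRInterface, sub_id: str, plan: IRPlan) -> SubCommand:
    return SubCommand(
        id=sub_id,
        doc="",
        command_template=_template_from_plan(ir, plan),
        params=[_param_from_ir(ir, ir.params[p]) for p in plan.param_paths],
    )


def descriptor_from_ir(ir: IRInterface) -> ToolDescriptor:
    params = [_param_from_ir(ir, ir.params[p]) for p in ir.plan.param_paths]
    outputs = []
    for o in ir.outputs:
        pieces = []
        strip: list[str] = []
        for part in o.parts:
            if isinstance(part, IROutLiteral):
                pieces.append(part.text)
            else:
                pieces.append(default_value_key(ir.params[part.path].id))
                if part.strip and not strip:
                    strip = list(part.strip)
        outputs.append(OutputSpec(
            id=o.id,
            doc=o.doc,
            path_template="".join(pieces),
            stripped_extensions=strip,
            optional=o.optional,
        ))
    return ToolDescriptor(
        name=ir.doc.title or ir.uid,
        id=ir.doc.original_id or ir.uid,
        doc=ir.doc.description,
        authors=list(ir.doc.authors),
        url=ir.doc.url,
        tool_version=ir.doc.tool_version,
        container=ir.container,
        command_template=_template_from_plan(ir, ir.plan),
        params=params,
        outputs=outputs,
        groups=list(ir.groups),
    )


def emit_descriptor(ir: IRInterface) -> str:
    """Serialize the IR back to dialect JSON; argv-equivalent to the source."""
    return serialize_descriptor(descriptor_from_ir(ir))
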