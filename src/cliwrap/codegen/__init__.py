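"""Code generation: IR -> wrapper source trees, and IR -> descriptor JSON.

Also provides the glue the oracle-equivalence suites rely on:
``assignment_to_native`` converts an interpreter assignment (param-id keyed)
into the shape generated wrappers take (legal-name keyed, ``__tag`` unions),
and ``load_host_tree``/``call_host_wrapper`` execute a generated host-dialect
tree in-process so its dry-run argv can be compared with the interpreter's.
"""

from __future__ import annotations

import importlib.util
import sys
from pathlib import Path
from types import ModuleType
from typing import Any, Mapping

from ..ir import IRInterface, IRParam
from ..model import ParamType
from .descriptor_backend import descriptor_from_ir, emit_descriptor
from .emitter import SourceTree, generate
from .profiles import COMPANION, HOST, PROFILES, DialectProfile, get_profile

__all__ = [
    "COMPANION",
    "HOST",
    "PROFILES",
    "DialectProfile",
    "SourceTree",
    "assignment_to_native",
    "call_host_wrapper",
    "descriptor_from_ir",
    "emit_descriptor",
    "generate",
    "get_profile",
    "load_host_tree",
    "write_tree",
]


def write_tree(tree: SourceTree, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for rel, text in sorted(tree.items()):
        p = directory / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text, "utf-8")
        written.append(p)
    return written


def _convert_value(ir: IRInterface, irp: IRParam, v: Any) -> Any:
    from ..interpreter import _unwrap_subcommand  # shared spelling rules

    vm = irp.value_model
    if vm.type is ParamType.UNION:
        (tag, sub), = v.items()
        plan = irp.nested[tag]  # type: ignore[index]
        out = {"__tag": tag}
        out.update(_convert_level(ir, plan, sub))
        return out
    if vm.type is ParamType.SUBCOMMAND:
        sub = _unwrap_subcommand(irp, v)
        (_, plan), = irp.nested.items()  # type: ignore[union-attr]
        return _convert_level(ir, plan, sub)
    return v


def _convert_level(ir: IRInterface, plan, a: Mapping[str, Any]) -> dict:
    out: dict[str, Any] = {}
    for path in plan.param_paths:
        irp = ir.params[path]
        if irp.id not in a or a[irp.id] is None:
            continue
        v = a[irp.id]
        if irp.value_model.repeatable and irp.value_model.type.is_nested:
            out[irp.legal_name] = [_convert_value(ir, irp, e) for e in v]
        else:
            out[irp.legal_name] = _convert_value(ir, irp, v)
    return out


def assignment_to_native(ir: IRInterface, a: Mapping[str, Any]) -> dict:
    """Rewrite an id-keyed assignment into wrapper-call keyword arguments."""
    return _convert_level(ir, ir.plan, a)


_LOAD_COUNTER = 0


def load_host_tree(ir: IRInterface, tree: SourceTree, directory: str | Path) -> ModuleType:
    """Write a host-dialect tree to ``directory`` and import the tool module."""
    global _LOAD_COUNTER
    write_tree(tree, directory)
    directory = Path(directory)
    _LOAD_COUNTER += 1
    shim_name = "cliwrap_shim"
    spec = importlib.util.spec_from_file_location(shim_name, directory / "cliwrap_shim.py")
    shim = importlib.util.module_from_spec(spec)  # type: ignore[arg-type]
    sys.modules[shim_name] = shim
    spec.loader.exec_module(shim)  # type: ignore[union-attr]
    mod_name = f"_cliwrap_gen_{ir.uid}_{_LOAD_COUNTER}"
    spec2 = importlib.util.spec_from_file_location(mod_name, directory / f"{ir.uid}.py")
    mod = importlib.util.module_from_spec(spec2)  # type: ignore[arg-type]
    sys.modules[mod_name] = mod
    spec2.loader.exec_module(mod)  # type: ignore[union-attr]
    return mod


def call_host_wrapper(ir: IRInterface, mod: ModuleType, a: Mapping[str, Any]):
    """Drive a loaded host wrapper with an interpreter assignment via the
    generated dry runner; returns (argv tokens, outputs record)."""
    shim = sys.modules["cliwrap_shim"]
    runner = shim.DryRunner()
    kwargs = assignment_to_native(ir, a)
    fn = getattr(mod, ir.uid)
    record = fn(**kwargs, runner=runner)
    return list(runner.last_cargs), record
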