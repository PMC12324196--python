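"""Decoupled execution layer.

Runners are interchangeable adapters satisfying one small contract:
``new_execution(metadata)`` returns an execution offering
``translate_input(path)``, ``output_root()`` and ``run(cargs)``.  Argv
construction happens before and independently of any runner, so the token
list recorded by a dry run is byte-identical to the one a local run spawns
(and to a container plan's, modulo the documented input-path rewriting).

Every completed execution yields an :class:`ExecutionRecord`; records from
one session form a file-dependency graph whose edges connect a producer's
resolved output path to a later consumer's input path.  Actual container
engines are never invoked here — :func:`container_plan` returns the
engine-agnostic mount plan for inspection.
"""

from __future__ import annotations

import json
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import networkx as nx

from .errors import CliwrapError, ContainerPlanError, ToolExecutionError
from .interpreter import (
    OutputObject,
    _bound_value,
    _unwrap_subcommand,
    build_cargs,
    ensure_valid_assignment,
    resolve_outputs,
)
from .ir import IRInterface, IRPlan
from .model import ContainerSpec, ParamType

INPUT_MOUNT_ROOT = "/cliwrap_input"
OUTPUT_MOUNT_ROOT = "/cliwrap_output"


@dataclass
class ExitStatus:
    state: str                   # "not-run" | "ok" | "error"
    code: Optional[int] = None
    stdout_path: Optional[str] = None
    stderr_path: Optional[str] = None


@dataclass
class ExecutionRecord:
    seq: int
    uid: str
    cargs: list[str]
    input_paths: list[str]
    outputs: OutputObject
    status: ExitStatus
    wall_time_s: Optional[float] = None

    def output_paths(self) -> list[str]:
        return [self.outputs.path(name) for name in sorted(self.outputs.files)]

    def to_json_dict(self) -> dict:
        return {
            "seq": self.seq,
            "uid": self.uid,
            "cargs": self.cargs,
            "input_paths": self.input_paths,
            "output_root": self.outputs.root,
            "output_files": self.outputs.files,
            "status": {"state": self.status.state, "code": self.status.code},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ExecutionRecord":
        return cls(
            seq=d["seq"],
            uid=d["uid"],
            cargs=list(d["cargs"]),
            input_paths=list(d["input_paths"]),
            outputs=OutputObject(root=d["output_root"], files=dict(d["output_files"])),
            status=ExitStatus(state=d["status"]["state"], code=d["status"]["code"]),
        )


class Execution:
    """One tool invocation under a runner; paths are stable per execution."""

    def __init__(self, runner: "Runner", metadata: Mapping[str, Any], seq: int):
        self.runner = runner
        self.metadata = dict(metadata)
        self.seq = seq

    def translate_input(self, path: str) -> str:
        return path

    def output_root(self) -> str:
        uid = self.metadata.get("uid", "tool")
        return str(Path(self.runner.workdir) / f"{uid}_{self.seq}")

    def run(self, cargs: list[str]) -> ExitStatus:  # pragma: no cover - abstract
        raise NotImplementedError


class Runner:
    """Base adapter: allocates executions with strictly increasing sequence
    numbers and keeps (and optionally persists) the session's records."""

    execution_class = Execution

    def __init__(self, workdir: str | Path = ".", persist: bool = False):
        self.workdir = str(workdir)
        self.persist = persist
        self.records: list[ExecutionRecord] = []
        self._seq = 0

    def new_execution(self, metadata: Mapping[str, Any]) -> Execution:
        self._seq += 1
        return self.execution_class(self, metadata, self._seq)

    def add_record(self, record: ExecutionRecord) -> None:
        self.records.append(record)
        if self.persist:
            p = Path(self.workdir)
            p.mkdir(parents=True, exist_ok=True)
            out = p / f"{record.uid}_{record.seq}.record.json"
            out.write_text(json.dumps(record.to_json_dict(), indent=2,
                                      ensure_ascii=False) + "\n", "utf-8")


class _DryExecution(Execution):
    def run(self, cargs: list[str]) -> ExitStatus:
        return ExitStatus(state="not-run")


class DryRunner(Runner):
    """Builds and records everything; spawns nothing."""

    execution_class = _DryExecution


class _LocalExecution(Execution):
    def run(self, cargs: list[str]) -> ExitStatus:
        root = Path(self.output_root())
        try:
            root.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise CliwrapError(f"output root {root} is not writable: {exc}") from exc
        stdout_path = root / "stdout.log"
        stderr_path = root / "stderr.log"
        try:
            with open(stdout_path, "w") as out, open(stderr_path, "w") as err:
                # token list handed to the OS directly; no shell ever sees it
                proc = subprocess.run(cargs, stdout=out, stderr=err, shell=False)
        except FileNotFoundError as exc:
            raise CliwrapError(f"executable not found: {cargs[0]!r}") from exc
        state = "ok" if proc.returncode == 0 else "error"
        return ExitStatus(state=state, code=proc.returncode,
                          stdout_path=str(stdout_path), stderr_path=str(stderr_path))


class LocalRunner(Runner):
    execution_class = _LocalExecution


def collect_input_paths(ir: IRInterface, a: Mapping[str, Any]) -> list[str]:
    """File-typed bound values in emission order (nested levels included)."""
    found: list[str] = []

    def walk(plan: IRPlan, scope: Mapping[str, Any]) -> None:
        for path in plan.param_paths:
            irp = ir.params[path]
            vm = irp.value_model
            v = _bound_value(vm, scope, irp.id)
            if v is None:
                continue
            if vm.type is ParamType.FILE:
                for item in (v if vm.repeatable else [v]):
                    if item not in found:
                        found.append(item)
            elif vm.type.is_nested:
                for item in (v if vm.repeatable else [v]):
                    if vm.type is ParamType.UNION:
                        (tag, sub), = item.items()
                        walk(irp.nested[tag], sub)  # type: ignore[index]
                    else:
                        sub = _unwrap_subcommand(irp, item)
                        (_, subplan), = irp.nested.items()  # type: ignore[union-attr]
                        walk(subplan, sub)

    walk(ir.plan, a)
    return found


def _metadata(ir: IRInterface) -> dict:
    return {"uid": ir.uid, "name": ir.doc.title}


def _execute(ir: IRInterface, a: Mapping[str, Any], runner: Runner) -> ExecutionRecord:
    ensure_valid_assignment(ir, a)
    cargs = build_cargs(ir, a)
    execution = runner.new_execution(_metadata(ir))
    outputs = resolve_outputs(ir, a, root=execution.output_root())
    inputs = collect_input_paths(ir, a)
    t0 = time.monotonic()
    status = execution.run(cargs)
    record = ExecutionRecord(
        seq=execution.seq,
        uid=ir.uid,
        cargs=cargs,
        input_paths=inputs,
        outputs=outputs,
        status=status,
        wall_time_s=time.monotonic() - t0,
    )
    runner.add_record(record)
    if status.state == "error":
        tail = ""
        if status.stderr_path:
            try:
                tail = Path(status.stderr_path).read_text("utf-8")[-2000:]
            except OSError:
                tail = ""
        raise ToolExecutionError(cargs, status.code or 1, tail)
    return record


def dry_run(ir: IRInterface, a: Mapping[str, Any],
            runner: Optional[DryRunner] = None) -> ExecutionRecord:
    """Record argv and resolved outputs without spawning a process."""
    return _execute(ir, a, runner if runner is not None else DryRunner())


def local_run(ir: IRInterface, a: Mapping[str, Any],
              runner: Optional[LocalRunner] = None) -> ExecutionRecord:
    """Spawn the tool directly from the token list (never via a shell)."""
    return _execute(ir, a, runner if runner is not None else LocalRunner())


# --------------------------------------------------------------------------
# container plans
# --------------------------------------------------------------------------

@dataclass
class Mount:
    host_path: str
    container_path: str
    read_only: bool


@dataclass
class MountPlan:
    """Engine-agnostic sandbox plan: read-only input mounts, one writable
    output root, and the argv rewritten onto container paths."""

    image: str
    mounts: list[Mount]
    cargs: list[str]
    output_root: str = OUTPUT_MOUNT_ROOT


def container_plan(ir: IRInterface, a: Mapping[str, Any],
                   spec: Optional[ContainerSpec] = None) -> MountPlan:
    """Plan a sandboxed invocation; no engine is ever invoked.

    Each distinct input file is mounted read-only at
    ``/cliwrap_input/<k>/<basename>`` (the index disambiguates duplicate
    basenames); outputs go to the single writable ``/cliwrap_output`` mount.
    """
    spec = spec if spec is not None else ir.container
    if spec is None:
        raise ContainerPlanError(f"descriptor '{ir.uid}' declares no container image")
    ensure_valid_assignment(ir, a)
    cargs = build_cargs(ir, a)
    inputs = collect_input_paths(ir, a)
    mounts = []
    translation: dict[str, str] = {}
    for k, host in enumerate(inputs, start=1):
        base = host.rsplit("/", 1)[-1]
        cpath = f"{INPUT_MOUNT_ROOT}/{k}/{base}"
        mounts.append(Mount(host_path=host, container_path=cpath, read_only=True))
        translation[host] = cpath
    mounts.append(Mount(host_path=".", container_path=OUTPUT_MOUNT_ROOT, read_only=False))
    image = spec.image + (f":{spec.tag}" if spec.tag else "")
    rewritten = [translation.get(tok, tok) for tok in cargs]
    return MountPlan(image=image, mounts=mounts, cargs=rewritten)


# --------------------------------------------------------------------------
# dependency graphs
# --------------------------------------------------------------------------

@dataclass
class DependencyGraph:
    nodes: list[ExecutionRecord] = field(default_factory=list)
    edges: list[tuple[int, int, str]] = field(default_factory=list)  # (producer seq, consumer seq, path)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for r in self.nodes:
            g.add_node(r.seq, uid=r.uid)
        for p, c, path in self.edges:
            g.add_edge(p, c, path=path)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(nx.DiGraph(self.to_networkx()))


def graph_collect(records: list[ExecutionRecord]) -> DependencyGraph:
    """Edges are exactly the (producer, consumer, path) triples where a
    consumer input path equals an earlier producer's resolved output path."""
    producers: dict[str, list[int]] = {}
    by_seq = {r.seq: r for r in records}
    for r in records:
        for path in r.output_paths():
            producers.setdefault(path, []).append(r.seq)
    edges: list[tuple[int, int, str]] = []
    for r in records:
        for path in r.input_paths:
            for pseq in producers.get(path, []):
                if pseq < r.seq:
                    edges.append((pseq, r.seq, path))
    edges.sort()
    nodes = sorted(records, key=lambda r: r.seq)
    graph = DependencyGraph(nodes=nodes, edges=edges)
    assert graph.is_acyclic()  # guaranteed by increasing sequence numbers
    return graph


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def graph_render(graph: DependencyGraph) -> str:
    """Deterministic DOT text; node labels are tool uid + sequence number."""
    lines = ["digraph dependencies {"]
    names = {}
    for r in graph.nodes:
        name = f"{r.uid}_{r.seq}"
        names[r.seq] = name
        lines.append(f"  {_dot_quote(name)} [label={_dot_quote(f'{r.uid} #{r.seq}')}];")
    for p, c, path in graph.edges:
        lines.append(f"  {_dot_quote(names[p])} -> {_dot_quote(names[c])} "
                     f"[label={_dot_quote(path)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def load_session(directory: str | Path) -> list[ExecutionRecord]:
    """Load persisted records (``*.record.json``) from a session directory."""
    records = []
    for p in sorted(Path(directory).glob("*.record.json")):
        records.append(ExecutionRecord.from_json_dict(json.loads(p.read_text("utf-8"))))
    records.sort(key=lambda r: r.seq)
    return records


class TimingMiddleware:
    """Experimental resource-profiling middleware: wraps any runner and
    stores wall-clock duration per sequence number.  Interface may change."""

    def __init__(self, inner: Runner):
        self.inner = inner
        self.timings: dict[int, float] = {}

    def new_execution(self, metadata: Mapping[str, Any]):
        ex = self.inner.new_execution(metadata)
        outer = self

        class _Timed:
            def translate_input(self, path: str) -> str:
                return ex.translate_input(path)

            def output_root(self) -> str:
                return ex.output_root()

            @property
            def seq(self):
                return ex.seq

            def run(self, cargs: list[str]) -> ExitStatus:
                t0 = time.monotonic()
                try:
                    return ex.run(cargs)
                finally:
                    outer.timings[ex.seq] = time.monotonic() - t0

        return _Timed()

    @property
    def records(self):
        return self.inner.records

    @property
    def workdir(self):
        return self.inner.workdir

    def add_record(self, record: ExecutionRecord) -> None:
        self.inner.add_record(record)
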