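"""Authored and randomly generated fixtures.

The authored descriptors encode the grammar features one each: ``toycalc``
(the combined worked example: repetition over an alternation containing a
nested alternation), ``bet_like`` (classic flat descriptor), ``n4_like``
(hierarchy with a joined list), ``interp_like`` (alternation), ``kv_like``
(repetition with space/dash/unicode-bearing values), ``minimal`` (empty
interface).  ``echo_like``/``exit2`` are tiny portable scripts materialized
on demand for local-runner tests.

``random_descriptor``/``random_assignment`` are the seeded generators behind
the property suites: every generated descriptor validates cleanly and every
generated assignment passes ``check_assignment`` by construction.
"""

from __future__ import annotations

import os
import random
import stat
from importlib import resources
from pathlib import Path

from ..model import ToolDescriptor, parse_descriptor

FIXTURE_NAMES = ("toycalc", "bet_like", "n4_like", "interp_like", "kv_like", "minimal")

#: the worked example: toycalc with an add and a sub operation
TOYCALC_EXAMPLE_ASSIGNMENT = {
    "input": "in.nii",
    "ops": [{"add": {"value": 5}}, {"sub": {"value": 3}}],
    "output": "out.nii",
}
TOYCALC_EXAMPLE_ARGV = ["toycalc", "in.nii", "-add", "5", "-sub", "3", "out.nii"]


def fixture_json(name: str) -> str:
    """Raw JSON text of a named fixture descriptor."""
    return (resources.files(__package__) / "data" / f"{name}.json").read_text("utf-8")


def fixture_descriptor(name: str) -> ToolDescriptor:
    """Parse (and therefore fully validate) a named fixture."""
    return parse_descriptor(fixture_json(name))


def write_fixture_dir(dst: str | Path) -> list[Path]:
    """Materialize every fixture descriptor as a JSON file under ``dst``."""
    dst = Path(dst)
    dst.mkdir(parents=True, exist_ok=True)
    out = []
    for name in FIXTURE_NAMES:
        p = dst / f"{name}.json"
        p.write_text(fixture_json(name), "utf-8")
        out.append(p)
    return out


# --------------------------------------------------------------------------
# executable fixtures (portable POSIX scripts, materialized at run time)
# --------------------------------------------------------------------------

_ECHO_SCRIPT = """\
#!/usr/bin/env python3
import sys
print(len(sys.argv) - 1)
for a in sys.argv[1:]:
    print(a)
"""

_EXIT2_SCRIPT = """\
#!/usr/bin/env python3
import sys
print("deliberate failure", file=sys.stderr)
sys.exit(2)
"""


def _write_script(directory: str | Path, name: str, body: str) -> Path:
    p = Path(directory) / name
    p.write_text(body, "utf-8")
    p.chmod(p.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
    return p


def write_echo_script(directory: str | Path) -> Path:
    """An argv printer: first line is the argument count, then one per line."""
    return _write_script(directory, "echo_like", _ECHO_SCRIPT)


def write_exit2_script(directory: str | Path) -> Path:
    """A tool that always fails with status 2."""
    return _write_script(directory, "exit2", _EXIT2_SCRIPT)


def echo_like_descriptor(script_path: str | Path) -> ToolDescriptor:
    """Descriptor wrapping the materialized echo script (repeatable string args)."""
    import json

    doc = {
        "name": "echo-like",
        "id": "echo_like",
        "command-line": f"{script_path} [ARGS]",
        "inputs": [
            {"id": "args", "type": "String", "value-key": "[ARGS]",
             "optional": True, "list": True},
        ],
        "output-files": [],
    }
    return parse_descriptor(json.dumps(doc))


def exit2_descriptor(script_path: str | Path) -> ToolDescriptor:
    import json

    doc = {
        "name": "exit2",
        "id": "exit2",
        "command-line": f"{script_path}",
        "inputs": [],
        "output-files": [],
    }
    return parse_descriptor(json.dumps(doc))


# --------------------------------------------------------------------------
# random generators
# --------------------------------------------------------------------------

_WORDS = ["alpha", "beta", "gamma", "delta", "omega", "sigma", "kappa",
          "theta", "lambda2", "zeta", "mu", "nu"]
_STRING_POOL = ["plain", "with space", "-dashlead", "über", "naïve täst",
                "x1_y2", "CAPS", "dot.sep"]
_SAFE_STRING_POOL = ["plain", "solo", "caps", "token"]  # for joined lists
_FILE_POOL = ["data/scan.nii", "sub-01_T1w.nii.gz", "work dir/img.nii", "b0.mif"]


def _mk_scalar(rng: random.Random, pid: str, depth_bias: float) -> dict:
    kind = rng.choice(["String", "File", "Number", "NumberInt", "Flag"])
    inp: dict = {"id": pid, "value-key": f"[{pid.upper()}]"}
    if kind == "Flag":
        inp.update({"type": "Flag", "command-line-flag": f"--{pid}", "optional": True})
        return inp
    if kind == "File":
        inp["type"] = "File"
    elif kind == "String":
        inp["type"] = "String"
    else:
        inp["type"] = "Number"
        if kind == "NumberInt":
            inp["integer"] = True
    if rng.random() < 0.4:
        inp["command-line-flag"] = f"--{pid}"
    repeatable = rng.random() < 0.25
    optional = repeatable or rng.random() < 0.5
    if repeatable:
        inp["list"] = True
        if inp["type"] != "File" and rng.random() < 0.3:
            inp["list-separator"] = ","
    if optional:
        inp["optional"] = True
    if inp["type"] == "Number":
        if rng.random() < 0.3:
            lo, hi = sorted(rng.sample(range(-50, 51), 2))
            inp["minimum"], inp["maximum"] = lo, hi
        elif inp.get("integer") and rng.random() < 0.3:
            inp["value-choices"] = sorted(rng.sample(range(0, 20), 3))
    elif inp["type"] == "String" and rng.random() < 0.2:
        inp["value-choices"] = rng.sample(_SAFE_STRING_POOL, 2)
    if optional and not repeatable and rng.random() < 0.3:
        if "value-choices" in inp:
            inp["default-value"] = rng.choice(inp["value-choices"])
        elif inp["type"] == "String":
            inp["default-value"] = "dflt"
        elif inp["type"] == "File":
            inp["default-value"] = "default.nii"
        elif inp.get("integer"):
            lo = int(inp.get("minimum", -10))
            hi = int(inp.get("maximum", 10))
            inp["default-value"] = rng.randint(lo, hi)
        else:
            lo = inp.get("minimum", -10.0)
            hi = inp.get("maximum", 10.0)
            inp["default-value"] = round(rng.uniform(lo, hi), 3)
    return inp


def _mk_level(rng: random.Random, prefix: str, executable: str,
              n_params: int, depth: int, max_depth: int) -> dict:
    inputs = []
    for i in range(n_params):
        pid = f"{prefix}{_WORDS[i % len(_WORDS)]}{i}"
        roll = rng.random()
        if depth < max_depth and roll < 0.15:
            # union of 2-3 alternatives
            n_alt = rng.randint(2, 3)
            alts = []
            for j in range(n_alt):
                alt_id = f"{pid}_alt{j}"
                alts.append(_mk_level(
                    rng, f"{alt_id[:3]}{j}", f"-{alt_id}",
                    rng.randint(0, 2), depth + 1, max_depth))
                alts[-1]["id"] = alt_id
            inp = {"id": pid, "value-key": f"[{pid.upper()}]", "type": alts}
            if rng.random() < 0.5:
                inp["optional"] = True
                if rng.random() < 0.5:
                    inp["list"] = True
            inputs.append(inp)
        elif depth < max_depth and roll < 0.30:
            body = _mk_level(rng, f"{pid[:3]}s", f"--{pid}",
                             rng.randint(0, 2), depth + 1, max_depth)
            body["id"] = f"{pid}_body"
            inp = {"id": pid, "value-key": f"[{pid.upper()}]", "type": body}
            if rng.random() < 0.6:
                inp["optional"] = True
                if rng.random() < 0.4:
                    inp["list"] = True
            inputs.append(inp)
        else:
            inputs.append(_mk_scalar(rng, pid, depth / max(max_depth, 1)))
    tokens = [executable]
    for inp in inputs:
        if rng.random() < 0.15:
            tokens.append(f"-x{rng.randint(0, 9)}")
        tokens.append(inp["value-key"])
    return {"id": "L", "command-line": " ".join(tokens), "inputs": inputs}


def random_descriptor(seed: int, max_params: int = 6, max_depth: int = 3) -> ToolDescriptor:
    """A seeded, reproducible, always-valid descriptor exercising all param kinds."""
    if max_params < 1 or max_depth < 1:
        raise ValueError("bounds must be ≥ 1")
    rng = random.Random(seed)
    n = rng.randint(1, max_params)
    level = _mk_level(rng, "p", f"tool{seed}", n, 1, max_depth)
    doc: dict = {
        "name": f"random tool {seed}",
        "id": f"rand_{seed}",
        "description": f"Seeded synthetic descriptor (seed={seed}).",
        "command-line": level["command-line"],
        "inputs": level["inputs"],
        "output-files": [],
    }
    # outputs referencing top-level file/string params
    candidates = [i for i in level["inputs"]
                  if i.get("type") in ("File", "String") and not i.get("list")]
    for k in range(rng.randint(0, 2)):
        if candidates and rng.random() < 0.7:
            src = rng.choice(candidates)
            doc["output-files"].append({
                "id": f"out{k}",
                "path-template": f"{src['value-key']}_out{k}.nii.gz",
                "path-template-stripped-extensions": [".nii", ".nii.gz"],
                "optional": bool(src.get("optional")) and "default-value" not in src,
            })
        else:
            doc["output-files"].append({"id": f"out{k}", "path-template": f"log{k}.txt"})
    if rng.random() < 0.3:
        doc["container-image"] = {"type": "docker", "image": f"example/rand{seed}", "tag": "1"}
    import json as _json

    return parse_descriptor(_json.dumps(doc))


def _rand_scalar_value(rng: random.Random, p, joined: bool):
    from ..model import ParamType

    if p.choices is not None:
        return rng.choice(p.choices)
    if p.type is ParamType.INTEGER:
        lo = int(p.minimum) if p.minimum is not None else -99
        hi = int(p.maximum) if p.maximum is not None else 99
        return rng.randint(lo, hi)
    if p.type is ParamType.FLOAT:
        lo = p.minimum if p.minimum is not None else -99.0
        hi = p.maximum if p.maximum is not None else 99.0
        return round(rng.uniform(lo, hi), 4)
    if p.type is ParamType.FILE:
        return rng.choice(_FILE_POOL)
    pool = _SAFE_STRING_POOL if joined else _STRING_POOL
    return rng.choice(pool)


def _rand_level(rng: random.Random, params) -> dict:
    from ..model import ParamType

    a: dict = {}
    for p in params:
        if p.type is ParamType.FLAG:
            if rng.random() < 0.5:
                a[p.id] = rng.random() < 0.7
            continue
        bind = (not p.optional) or p.repeatable or rng.random() < 0.6
        if not bind:
            continue
        if p.type.is_nested:
            def one():
                alt = rng.choice(p.alternatives)
                body = _rand_level(rng, alt.params)
                return {alt.id: body} if p.type is ParamType.UNION else body
            if p.repeatable:
                a[p.id] = [one() for _ in range(rng.randint(0, 3))]
            else:
                a[p.id] = one()
        else:
            joined = p.join_separator is not None
            if p.repeatable:
                a[p.id] = [_rand_scalar_value(rng, p, joined)
                           for _ in range(rng.randint(0, 3))]
            else:
                a[p.id] = _rand_scalar_value(rng, p, joined)
    return a


def random_assignment(d: ToolDescriptor, seed: int) -> dict:
    """A seeded assignment guaranteed to pass check_assignment for ``d``."""
    rng = random.Random(seed)
    return _rand_level(rng, d.params)
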