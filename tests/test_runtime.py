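"""Runner contract, container plans, and dependency-graph provenance."""

import itertools
import json
from pathlib import Path

import pytest

from cliwrap import lower, optimize
from cliwrap.errors import CliwrapError, ContainerPlanError, ToolExecutionError
from cliwrap.fixtures import (
    TOYCALC_EXAMPLE_ARGV,
    TOYCALC_EXAMPLE_ASSIGNMENT,
    echo_like_descriptor,
    exit2_descriptor,
    fixture_descriptor,
    write_echo_script,
    write_exit2_script,
)
from cliwrap.runtime import (
    DryRunner,
    LocalRunner,
    TimingMiddleware,
    container_plan,
    dry_run,
    graph_collect,
    graph_render,
    load_session,
    local_run,
)


def pairwise_oracle(records):
    """Independent O(n²) edge oracle: exhaustive pairwise path intersection."""
    edges = []
    for p, c in itertools.permutations(records, 2):
        if p.seq >= c.seq:
            continue
        for path in p.output_paths():
            for ipath in c.input_paths:
                if path == ipath:
                    edges.append((p.seq, c.seq, path))
    return sorted(edges)


class TestDryRun:
    def test_worked_example_record(self, toycalc_ir, tmp_path):
        rec = dry_run(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT, DryRunner(tmp_path))
        assert rec.cargs == TOYCALC_EXAMPLE_ARGV
        assert rec.status.state == "not-run"
        assert rec.input_paths == ["in.nii"]
        assert rec.outputs.files == {"out_file": "out.nii"}

    def test_sequence_numbers_increase(self, minimal_ir, tmp_path):
        r = DryRunner(tmp_path)
        assert dry_run(minimal_ir, {}, r).seq == 1
        assert dry_run(minimal_ir, {}, r).seq == 2

    def test_minimal_record(self, minimal_ir, tmp_path):
        assert dry_run(minimal_ir, {}, DryRunner(tmp_path)).cargs == ["true"]

    def test_output_root_is_uid_and_seq(self, toycalc_ir, tmp_path):
        rec = dry_run(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT, DryRunner(tmp_path))
        assert rec.outputs.root == str(tmp_path / "toycalc_1")


class TestLocalRun:
    def test_no_shell_tokens_with_spaces_survive(self, tmp_path):
        script = write_echo_script(tmp_path)
        ir = optimize(lower(echo_like_descriptor(script)))
        rec = local_run(ir, {"args": ["a b", "c"]}, LocalRunner(tmp_path))
        lines = Path(rec.status.stdout_path).read_text("utf-8").splitlines()
        assert lines == ["2", "a b", "c"]

    def test_nonzero_exit_surfaces_structured_error(self, tmp_path):
        script = write_exit2_script(tmp_path)
        ir = optimize(lower(exit2_descriptor(script)))
        runner = LocalRunner(tmp_path)
        with pytest.raises(ToolExecutionError) as err:
            local_run(ir, {}, runner)
        assert err.value.returncode == 2
        assert err.value.cargs == [str(script)]
        assert runner.records[-1].status.code == 2

    def test_missing_executable(self, tmp_path):
        ir = optimize(lower(exit2_descriptor(tmp_path / "definitely-not-here")))
        with pytest.raises(CliwrapError, match="not found"):
            local_run(ir, {}, LocalRunner(tmp_path))

    def test_dry_and_local_argv_identical(self, tmp_path):
        script = write_echo_script(tmp_path)
        ir = optimize(lower(echo_like_descriptor(script)))
        a = {"args": ["x", "y z"]}
        dry = dry_run(ir, a, DryRunner(tmp_path))
        wet = local_run(ir, a, LocalRunner(tmp_path))
        assert dry.cargs == wet.cargs


class TestContainerPlan:
    def test_duplicate_basenames_disambiguated_by_index(self):
        ir = optimize(lower(fixture_descriptor("kv_like")))
        # two file tokens sharing a basename via entries is not possible in
        # kv_like; use toycalc twice through a two-input synthetic descriptor
        from cliwrap import parse_descriptor

        d = parse_descriptor(
            '{"name":"m","command-line":"m [A] [B]","inputs":['
            '{"id":"a","type":"File","value-key":"[A]"},'
            '{"id":"b","type":"File","value-key":"[B]"}],'
            '"container-image":{"type":"docker","image":"img","tag":"1"}}')
        plan = container_plan(lower(d), {"a": "a/x.nii", "b": "b/x.nii"})
        inputs = [m for m in plan.mounts if m.read_only]
        assert [m.container_path for m in inputs] == [
            "/cliwrap_input/1/x.nii", "/cliwrap_input/2/x.nii"]
        assert plan.cargs == ["m", "/cliwrap_input/1/x.nii", "/cliwrap_input/2/x.nii"]

    def test_zero_file_inputs_only_output_mount(self, minimal_ir):
        from cliwrap import parse_descriptor

        d = parse_descriptor(
            '{"name":"t","command-line":"t","inputs":[],'
            '"container-image":{"type":"docker","image":"img"}}')
        plan = container_plan(lower(d), {})
        assert len(plan.mounts) == 1
        assert plan.mounts[0].container_path == "/cliwrap_output"
        assert not plan.mounts[0].read_only

    def test_sandbox_property(self, bet_ir):
        a = {"input": "data/t1 scan.nii", "output": "brain", "binary_mask": True}
        plan = container_plan(bet_ir, a)
        file_tokens = [t for t in plan.cargs if "/" in t and t != "bet"]
        for tok in file_tokens:
            assert tok.startswith("/cliwrap_input/") or tok.startswith("/cliwrap_output")
        for m in plan.mounts[:-1]:
            assert m.read_only

    def test_absent_container_spec_is_an_error(self, toycalc_ir):
        with pytest.raises(ContainerPlanError):
            container_plan(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT)

    def test_argv_identical_to_dry_run_modulo_rewrite(self, bet_ir, tmp_path):
        a = {"input": "t1.nii", "output": "brain"}
        dry = dry_run(bet_ir, a, DryRunner(tmp_path))
        plan = container_plan(bet_ir, a)
        back = [("t1.nii" if t == "/cliwrap_input/1/t1.nii" else t) for t in plan.cargs]
        assert back == dry.cargs


def _chain_session(tmp_path, n=3):
    """Stage k consumes stage k-1's resolved output; one shared dry session."""
    from cliwrap import parse_descriptor

    runner = DryRunner(tmp_path, persist=True)
    prev_out = "seed/start.nii"
    for k in range(n):
        d = parse_descriptor(json.dumps({
            "name": f"stage{k}", "command-line": f"stage{k} [IN] [OUT]",
            "inputs": [
                {"id": "in_file", "type": "File", "value-key": "[IN]"},
                {"id": "out_name", "type": "String", "value-key": "[OUT]"},
            ],
            "output-files": [{"id": "result", "path-template": "[OUT].nii"}],
        }))
        ir = optimize(lower(d))
        rec = dry_run(ir, {"in_file": prev_out, "out_name": "img"}, runner)
        prev_out = rec.outputs.path("result")
    return runner


class TestDependencyGraph:
    def test_three_stage_chain_has_two_edges(self, tmp_path):
        runner = _chain_session(tmp_path)
        g = graph_collect(runner.records)
        assert len(g.edges) == 2
        assert g.edges == pairwise_oracle(runner.records)

    def test_independent_records_no_edges(self, minimal_ir, tmp_path):
        r = DryRunner(tmp_path)
        dry_run(minimal_ir, {}, r)
        dry_run(minimal_ir, {}, r)
        g = graph_collect(r.records)
        assert g.edges == [] == pairwise_oracle(r.records)

    def test_diamond_two_consumers_of_one_output(self, tmp_path, bet_ir):
        r = DryRunner(tmp_path)
        producer = dry_run(bet_ir, {"input": "t1.nii", "output": "brain"}, r)
        shared = producer.outputs.path("outfile")
        for _ in range(2):
            dry_run(bet_ir, {"input": shared, "output": "next"}, r)
        g = graph_collect(r.records)
        assert len(g.edges) == 2
        assert all(e[0] == producer.seq for e in g.edges)
        assert g.edges == pairwise_oracle(r.records)

    def test_graph_matches_oracle_on_session_with_mixed_links(self, tmp_path):
        runner = _chain_session(tmp_path, n=4)
        from cliwrap.fixtures import fixture_descriptor as fd

        ir = optimize(lower(fd("minimal")))
        dry_run(ir, {}, runner)  # unlinked straggler
        g = graph_collect(runner.records)
        assert g.edges == pairwise_oracle(runner.records)
        assert g.is_acyclic()

    def test_dot_rendering_deterministic_with_labels(self, tmp_path):
        runner = _chain_session(tmp_path)
        g = graph_collect(runner.records)
        dot1 = graph_render(g)
        dot2 = graph_render(graph_collect(load_session(tmp_path)))
        assert dot1 == dot2
        assert dot1.startswith("digraph")
        assert '"stage0_1"' in dot1 and "->" in dot1


def test_timing_middleware_records_durations(minimal_ir, tmp_path):
    mw = TimingMiddleware(DryRunner(tmp_path))
    rec = dry_run(minimal_ir, {}, mw)
    assert rec.seq in mw.timings
    assert mw.timings[rec.seq] >= 0
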