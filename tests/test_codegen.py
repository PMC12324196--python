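"""Wrapper generation: oracle equivalence, determinism, round-trips, goldens."""

import dataclasses
import subprocess
import sys
from pathlib import Path

import pytest

from cliwrap import build_cargs, lower, optimize, parse_descriptor
from cliwrap.codegen import (
    COMPANION,
    HOST,
    assignment_to_native,
    call_host_wrapper,
    emit_descriptor,
    generate,
    get_profile,
    load_host_tree,
    write_tree,
)
from cliwrap.errors import CodegenError
from cliwrap.fixtures import (
    TOYCALC_EXAMPLE_ARGV,
    TOYCALC_EXAMPLE_ASSIGNMENT,
    fixture_descriptor,
    random_assignment,
    random_descriptor,
)

GOLDEN = Path(__file__).parent / "golden"


class TestHostGeneration:
    def test_worked_example_through_generated_wrapper(self, toycalc_ir, tmp_path):
        mod = load_host_tree(toycalc_ir, generate(toycalc_ir, HOST), tmp_path)
        argv, record = call_host_wrapper(toycalc_ir, mod, TOYCALC_EXAMPLE_ASSIGNMENT)
        assert argv == TOYCALC_EXAMPLE_ARGV
        assert record.out_file.endswith("/out.nii")
        assert hasattr(record, "root")

    def test_minimal_wrapper_emits_single_token(self, minimal_ir, tmp_path):
        mod = load_host_tree(minimal_ir, generate(minimal_ir, HOST), tmp_path)
        argv, _ = call_host_wrapper(minimal_ir, mod, {})
        assert argv == ["true"]

    def test_generation_is_byte_deterministic(self, toycalc_ir):
        assert generate(toycalc_ir, HOST) == generate(toycalc_ir, HOST)
        assert generate(toycalc_ir, COMPANION) == generate(toycalc_ir, COMPANION)

    def test_static_metadata_appears_in_documentation(self, toycalc_ir):
        code = generate(toycalc_ir, HOST)["toycalc.py"]
        assert "Constant to add" in code           # param doc
        assert "Toy image calculator" in code      # tool doc
        code_interp = generate(optimize(lower(fixture_descriptor("interp_like"))),
                               HOST)["interp_like.py"]
        assert "min 1" in code_interp and "max 5" in code_interp

    def test_no_shell_strings_constructed(self, toycalc_ir):
        code = generate(toycalc_ir, HOST)["toycalc.py"]
        assert "subprocess" not in code and "os.system" not in code
        assert '" ".join(cargs)' not in code

    def test_missing_template_reported_by_name(self, toycalc_ir):
        broken_templates = dict(HOST.templates)
        del broken_templates["append"]
        broken = dataclasses.replace(HOST, templates=broken_templates)
        with pytest.raises(CodegenError, match="append"):
            generate(toycalc_ir, broken)

    def test_unknown_profile_name(self):
        with pytest.raises(KeyError):
            get_profile("fortran")

    def test_oracle_equivalence_small_corpus(self, tmp_path):
        for seed in range(25):
            d = random_descriptor(seed)
            ir = optimize(lower(d))
            mod = load_host_tree(ir, generate(ir, HOST), tmp_path / str(seed))
            for k in range(3):
                a = random_assignment(d, seed * 101 + k)
                got, _ = call_host_wrapper(ir, mod, a)
                assert got == build_cargs(ir, a), (seed, k)


class TestDescriptorBackend:
    def test_minimal_round_trip_is_structural(self, minimal_ir):
        d2 = parse_descriptor(emit_descriptor(minimal_ir))
        assert d2 == fixture_descriptor("minimal")

    def test_toycalc_round_trip_argv_equivalent(self, toycalc, toycalc_ir):
        ir2 = lower(parse_descriptor(emit_descriptor(toycalc_ir)))
        for k in range(5):
            a = random_assignment(toycalc, k)
            assert build_cargs(toycalc_ir, a) == build_cargs(ir2, a), k
        assert build_cargs(ir2, TOYCALC_EXAMPLE_ASSIGNMENT) == TOYCALC_EXAMPLE_ARGV

    def test_seeded_round_trip_corpus(self):
        for seed in range(40):
            d = random_descriptor(seed)
            ir = optimize(lower(d))
            ir2 = lower(parse_descriptor(emit_descriptor(ir)))
            for k in range(2):
                a = random_assignment(d, seed * 7 + k)
                assert build_cargs(ir, a) == build_cargs(ir2, a), (seed, k)


class TestCompanion:
    def test_golden_files_regenerate_byte_identically(self, toycalc_ir, minimal_ir):
        tree = generate(toycalc_ir, COMPANION)
        assert tree["toycalc.R"] == (GOLDEN / "toycalc.R").read_text("utf-8")
        assert tree["cliwrap_shim.R"] == (GOLDEN / "cliwrap_shim.R").read_text("utf-8")
        tree_min = generate(minimal_ir, COMPANION)
        assert tree_min["minimal_true.R"] == (GOLDEN / "minimal_true.R").read_text("utf-8")

    def test_live_smoke_reproduces_worked_example(self, toycalc_ir, tmp_path):
        write_tree(generate(toycalc_ir, COMPANION), tmp_path)
        driver = tmp_path / "driver.R"
        driver.write_text(
            f'source("{tmp_path}/cliwrap_shim.R")\n'
            f'source("{tmp_path}/toycalc.R")\n'
            "runner <- cliwrap_dry_runner()\n"
            'res <- toycalc(input = "in.nii",\n'
            "  ops = list(toycalc_ops_add(value = 5), toycalc_ops_sub(value = 3)),\n"
            '  output = "out.nii", runner = runner)\n'
            'cat(runner$last_cargs, sep = "\\n")\n')
        proc = subprocess.run(["Rscript", str(driver)], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        assert proc.stdout.splitlines() == TOYCALC_EXAMPLE_ARGV


def test_assignment_to_native_tags_unions(toycalc_ir):
    native = assignment_to_native(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT)
    assert native["ops"][0] == {"__tag": "add", "value": 5}
    assert native["input"] == "in.nii"
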