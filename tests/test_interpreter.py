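"""Reference argv semantics, assignment checking and output resolution."""

import pytest

from cliwrap import (
    build_cargs,
    check_assignment,
    lower,
    optimize,
    parse_descriptor,
    resolve_outputs,
)
from cliwrap.errors import OutputResolutionError
from cliwrap.fixtures import (
    TOYCALC_EXAMPLE_ARGV,
    TOYCALC_EXAMPLE_ASSIGNMENT,
    fixture_descriptor,
    random_assignment,
    random_descriptor,
)
from cliwrap.interpreter import format_value


class TestCheckAssignment:
    def test_empty_ops_is_legal(self, toycalc_ir):
        assert check_assignment(
            toycalc_ir, {"input": "in.nii", "output": "out.nii", "ops": []}) == []

    def test_missing_required_named_by_path(self, toycalc_ir):
        issues = check_assignment(toycalc_ir, {"input": "in.nii", "ops": []})
        assert len(issues) == 1 and issues[0].path == "output"

    def test_type_mismatch_inside_union(self, toycalc_ir):
        issues = check_assignment(toycalc_ir, {
            "input": "in.nii", "output": "o",
            "ops": [{"add": {"value": "five"}}]})
        assert any(i.path == "ops/add/value" for i in issues)

    def test_unknown_alternative_rejected(self, toycalc_ir):
        issues = check_assignment(toycalc_ir, {
            "input": "in.nii", "output": "o", "ops": [{"mul": {"value": 2}}]})
        assert any("mul" in i.message for i in issues)

    def test_bounds_and_choices(self):
        d = parse_descriptor(
            '{"name":"t","command-line":"t [A] [B]","inputs":['
            '{"id":"a","type":"Number","value-key":"[A]","minimum":0,"maximum":1},'
            '{"id":"b","type":"String","value-key":"[B]","value-choices":["x","y"]}]}')
        ir = lower(d)
        assert check_assignment(ir, {"a": 0.5, "b": "x"}) == []
        issues = check_assignment(ir, {"a": 2, "b": "z"})
        assert {i.path for i in issues} == {"a", "b"}

    def test_group_constraints(self):
        d = parse_descriptor(
            '{"name":"t","command-line":"t [A] [B]","inputs":['
            '{"id":"a","type":"String","value-key":"[A]","optional":true},'
            '{"id":"b","type":"String","value-key":"[B]","optional":true}],'
            '"groups":[{"id":"g","members":["a","b"],'
            '"mutually-exclusive":true,"one-is-required":true}]}')
        ir = lower(d)
        assert check_assignment(ir, {"a": "x"}) == []
        assert any("mutually exclusive" in i.message
                   for i in check_assignment(ir, {"a": "x", "b": "y"}))
        assert any("required" in i.message for i in check_assignment(ir, {}))


class TestBuildCargs:
    def test_worked_example(self, toycalc_ir):
        assert build_cargs(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT) == TOYCALC_EXAMPLE_ARGV

    def test_empty_repetition(self, toycalc_ir):
        a = {"input": "in.nii", "ops": [], "output": "out.nii"}
        assert build_cargs(toycalc_ir, a) == ["toycalc", "in.nii", "out.nii"]

    def test_nested_union_dispatch(self, toycalc_ir):
        a = {"input": "in.nii", "output": "out.nii",
             "ops": [{"complex": {"mode": {"option2": {"param1": "a", "param2": "b"}}}}]}
        assert build_cargs(toycalc_ir, a) == [
            "toycalc", "in.nii", "-complex", "option2", "a", "b", "out.nii"]

    def test_flag_emission_and_false_flag_silence(self, bet_ir):
        a = {"input": "t1.nii", "output": "brain", "binary_mask": True}
        assert build_cargs(bet_ir, a) == ["bet", "t1.nii", "brain", "-m"]
        a2 = {"input": "t1.nii", "output": "brain", "binary_mask": False}
        assert build_cargs(bet_ir, a2) == ["bet", "t1.nii", "brain"]

    def test_joined_list_renders_one_token(self):
        ir = optimize(lower(fixture_descriptor("n4_like")))
        a = {"input": "t1.nii", "output": "o",
             "convergence": {"iters": [50, 20, 10], "tol": 1e-06}}
        assert build_cargs(ir, a) == [
            "n4correct", "-i", "t1.nii", "-o", "o",
            "--convergence", "50x20x10", "1e-06"]

    def test_repetition_order_preserved_verbatim(self):
        ir = optimize(lower(fixture_descriptor("kv_like")))
        a = {"input": "x.nii", "output": "o",
             "entries": [{"key": "b", "val": "-2"}, {"key": "a", "val": "süß"}]}
        assert build_cargs(ir, a) == [
            "kvtool", "x.nii", "-set", "b", "-2", "-set", "a", "süß", "o"]

    def test_tokens_with_spaces_survive_verbatim(self):
        ir = optimize(lower(fixture_descriptor("kv_like")))
        a = {"input": "work dir/img.nii", "output": "o",
             "entries": [{"key": "note", "val": "two words"}]}
        argv = build_cargs(ir, a)
        assert "work dir/img.nii" in argv and "two words" in argv

    def test_deterministic(self, toycalc_ir):
        runs = {tuple(build_cargs(toycalc_ir, TOYCALC_EXAMPLE_ASSIGNMENT))
                for _ in range(5)}
        assert len(runs) == 1

    @pytest.mark.parametrize("value,token", [
        (5, "5"), (-3, "-3"), (0.5, "0.5"), (1e-06, "1e-06"), (2.0, "2.0"),
    ])
    def test_number_formatting(self, value, token):
        assert format_value(value) == token


class TestResolveOutputs:
    def test_simple_substitution(self, bet_ir):
        out = resolve_outputs(bet_ir, {"input": "t1.nii", "output": "brain"}, root="r")
        assert out.files["outfile"] == "brain.nii.gz"
        assert out.path("outfile") == "r/brain.nii.gz"

    def test_longest_suffix_strip_and_basename(self):
        ir = optimize(lower(fixture_descriptor("n4_like")))
        out = resolve_outputs(ir, {"input": "dir/sub-01_T1w.nii.gz", "output": "o"})
        assert out.files["corrected"] == "sub-01_T1w_corrected.nii.gz"

    def test_literal_only_template(self):
        d = parse_descriptor(
            '{"name":"t","command-line":"t","inputs":[],'
            '"output-files":[{"id":"log","path-template":"log.txt"}]}')
        assert resolve_outputs(lower(d), {}).files["log"] == "log.txt"

    def test_unbound_optional_param_omits_optional_output(self):
        d = parse_descriptor(
            '{"name":"t","command-line":"t [A]","inputs":['
            '{"id":"a","type":"String","value-key":"[A]","optional":true}],'
            '"output-files":[{"id":"o","path-template":"[A].txt","optional":true}]}')
        ir = lower(d)
        assert resolve_outputs(ir, {}).files == {}
        assert resolve_outputs(ir, {"a": "x"}).files == {"o": "x.txt"}

    def test_unbound_required_output_is_an_error(self):
        d = parse_descriptor(
            '{"name":"t","command-line":"t [A]","inputs":['
            '{"id":"a","type":"String","value-key":"[A]","optional":true}],'
            '"output-files":[{"id":"o","path-template":"[A].txt"}]}')
        with pytest.raises(OutputResolutionError):
            resolve_outputs(lower(d), {})


def test_generated_assignments_always_check_clean():
    for seed in range(50):
        d = random_descriptor(seed)
        ir = lower(d)
        for k in range(3):
            a = random_assignment(d, seed + 1000 * k)
            assert check_assignment(ir, a) == [], (seed, k)
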