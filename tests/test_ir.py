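"""Lowering, optimization and identifier mangling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cliwrap import build_cargs, lower, mangle, optimize, parse_descriptor
from cliwrap.errors import MangleError
from cliwrap.fixtures import random_assignment, random_descriptor
from cliwrap.ir import IRCarg, IRLiteral, IRRef, ir_to_debug_dict
from cliwrap.model import ParamType


class TestMangle:
    @pytest.mark.parametrize("raw,expected", [
        ("bet", "bet"),
        ("3dcalc", "v_3dcalc"),
        ("N4BiasFieldCorrection", "n4biasfieldcorrection"),
        ("-add", "add"),
        ("for", "for_"),          # reserved in a shipped dialect
        ("TRUE", "true_"),
        ("a--b__c", "a_b_c"),
    ])
    def test_rules(self, raw, expected):
        assert mangle(raw, set()) == expected

    def test_collision_gets_numeric_suffix(self):
        used = {"add"}
        assert mangle("-add", used) == "add_2"
        assert mangle("add", used) == "add_3"

    def test_entirely_nonalphanumeric_rejected(self):
        with pytest.raises(MangleError):
            mangle("--//--", set())

    @given(st.lists(st.text(alphabet="abz09-_A", min_size=1, max_size=8), max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_injective_per_used_set(self, raws):
        used: set[str] = set()
        seen = []
        for raw in raws:
            try:
                seen.append(mangle(raw, used))
            except MangleError:
                pass
        assert len(seen) == len(set(seen))


class TestLower:
    def test_toycalc_plan_shape(self, toycalc, toycalc_ir):
        ir = toycalc_ir
        parts = [c.parts[0] for c in ir.plan.cargs]
        assert isinstance(parts[0], IRLiteral) and parts[0].text == "toycalc"
        refs = [p.path for p in parts[1:]]
        assert refs == ["input", "ops", "output"]
        assert ir.uid == "toycalc"

    def test_minimal_plan(self, minimal_ir):
        assert len(minimal_ir.plan.cargs) == 1
        assert minimal_ir.plan.cargs[0].parts[0].text == "true"
        assert minimal_ir.params == {}

    def test_bet_flag_lowered_with_token(self, bet_ir):
        vm = bet_ir.params["binary_mask"].value_model
        assert vm.type is ParamType.FLAG and vm.flag_token == "-m"

    def test_paths_are_slash_joined_across_levels(self, toycalc_ir):
        assert "ops/complex/mode/option2/param2" in toycalc_ir.params

    def test_no_user_settable_slot_lost(self):
        for seed in range(30):
            d = random_descriptor(seed)

            def count(params):
                n = 0
                for p in params:
                    n += 1
                    for alt in p.alternatives:
                        n += count(alt.params)
                return n

            assert lower(d).user_settable_count() == count(d.params), seed

    def test_debug_dump_is_json_shaped(self, toycalc_ir):
        import json

        dump = ir_to_debug_dict(toycalc_ir)
        assert json.loads(json.dumps(dump)) == dump
        assert dump["uid"] == "toycalc"


class TestOptimize:
    def test_adjacent_literal_parts_merge_into_one_token(self, minimal_ir):
        import copy

        ir = copy.deepcopy(minimal_ir)
        ir.plan.cargs.append(IRCarg([IRLiteral("-"), IRLiteral("add")]))
        out = optimize(ir)
        assert out.plan.cargs[-1].parts == [IRLiteral("-add")]
        assert build_cargs(out, {}) == ["true", "-add"]

    def test_empty_carg_groups_dropped(self, minimal_ir):
        import copy

        ir = copy.deepcopy(minimal_ir)
        ir.plan.cargs.append(IRCarg([]))
        assert len(optimize(ir).plan.cargs) == 1

    def test_single_alternative_union_hoisted(self):
        # constructed programmatically: validate() would reject a 1-alt union
        doc = {
            "name": "t", "command-line": "t [X]",
            "inputs": [{"id": "x", "value-key": "[X]",
                        "type": [
                            {"id": "a", "command-line": "-a [V]",
                             "inputs": [{"id": "v", "type": "String", "value-key": "[V]"}]},
                            {"id": "b", "command-line": "-b", "inputs": []}]}],
        }
        import json

        ir = lower(parse_descriptor(json.dumps(doc)))
        ir.params["x"].nested.pop("b")
        out = optimize(ir)
        assert out.params["x"].value_model.type is ParamType.SUBCOMMAND
        # tagged and plain spellings now agree
        assert build_cargs(out, {"x": {"a": {"v": "s"}}}) == ["t", "-a", "s"]
        assert build_cargs(out, {"x": {"v": "s"}}) == ["t", "-a", "s"]

    def test_idempotent(self, toycalc_ir):
        assert optimize(toycalc_ir) == optimize(optimize(toycalc_ir))

    def test_argv_equivalence_on_seeded_corpus(self):
        for seed in range(60):
            d = random_descriptor(seed)
            ir = lower(d)
            oir = optimize(ir)
            for k in range(3):
                a = random_assignment(d, seed * 31 + k)
                assert build_cargs(ir, a) == build_cargs(oir, a), (seed, k)
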