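"""Descriptor dialect: parsing, validation, serialization, round-trips."""

import json

import pytest

from cliwrap.errors import (
    CrossReferenceError,
    DescriptorParseError,
    DescriptorValidationError,
)
from cliwrap.fixtures import (
    FIXTURE_NAMES,
    fixture_descriptor,
    fixture_json,
    random_descriptor,
)
from cliwrap.model import (
    ParamType,
    parse_descriptor,
    serialize_descriptor,
    validate,
)

MINIMAL = '{"name": "true", "command-line": "true", "inputs": [], "output-files": []}'


class TestParse:
    def test_toycalc_shape(self, toycalc):
        assert [p.id for p in toycalc.params] == ["input", "ops", "output"]
        ops = toycalc.params[1]
        assert ops.type is ParamType.UNION
        assert ops.repeatable and ops.optional
        assert [a.id for a in ops.alternatives] == ["add", "sub", "complex"]

    def test_minimal_descriptor_is_valid(self):
        d = parse_descriptor(MINIMAL)
        assert d.name == "true"
        assert d.params == [] and d.outputs == []
        assert [t.text for t in d.command_template] == ["true"]

    def test_malformed_json_reports_position(self):
        with pytest.raises(DescriptorParseError) as err:
            parse_descriptor('{"name": "x", }')
        assert err.value.line == 1 and err.value.column is not None

    def test_renamed_placeholder_names_the_dangling_param(self):
        doc = json.loads(fixture_json("toycalc"))
        doc["command-line"] = "toycalc [INPUT] [OPSX] [OUTPUT]"
        with pytest.raises(CrossReferenceError) as err:
            parse_descriptor(json.dumps(doc))
        assert "ops" in str(err.value)

    def test_shape_errors_use_json_pointers(self):
        with pytest.raises(DescriptorValidationError) as err:
            parse_descriptor('{"name": "x", "command-line": "x", "inputs": [{"id": ""}]}')
        assert any(i.path.startswith("/inputs/0") for i in err.value.issues)

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_all_shipped_fixtures_parse_clean(self, name):
        assert validate(fixture_descriptor(name)) == []


class TestValidate:
    def _desc(self, **extra_input):
        doc = {
            "name": "t", "command-line": "t [X]",
            "inputs": [{"id": "x", "type": "Number", "value-key": "[X]", **extra_input}],
            "output-files": [],
        }
        return json.dumps(doc)

    def test_inverted_bounds_flagged_at_param_path(self):
        with pytest.raises(DescriptorValidationError) as err:
            parse_descriptor(self._desc(minimum=5, maximum=2))
        issues = err.value.issues
        assert len(issues) == 1
        assert issues[0].path == "/inputs/0/minimum"

    def test_union_requires_two_alternatives(self):
        doc = {
            "name": "t", "command-line": "t [X]",
            "inputs": [{"id": "x", "value-key": "[X]",
                        "type": [{"id": "a", "command-line": "-a", "inputs": []}]}],
        }
        with pytest.raises(DescriptorValidationError) as err:
            parse_descriptor(json.dumps(doc))
        assert any("≥2 alternatives" in i.message for i in err.value.issues)

    def test_repeatable_must_be_optional(self):
        with pytest.raises(DescriptorValidationError) as err:
            parse_descriptor(self._desc(list=True))
        assert any("zero occurrences" in i.message for i in err.value.issues)

    def test_default_checked_against_choices_and_bounds(self):
        with pytest.raises(DescriptorValidationError):
            parse_descriptor(self._desc(**{"default-value": 9, "minimum": 0, "maximum": 5,
                                           "optional": True}))

    def test_depth_cap_enforced(self):
        inner: dict = {"id": "leaf", "command-line": "-leaf", "inputs": []}
        for k in range(12):
            inner = {"id": f"n{k}", "command-line": f"-n{k} [S{k}]",
                     "inputs": [{"id": f"s{k}", "value-key": f"[S{k}]", "type": inner}]}
        doc = {"name": "deep", "command-line": "deep [S]",
               "inputs": [{"id": "s", "value-key": "[S]", "type": inner}]}
        with pytest.raises(DescriptorValidationError) as err:
            parse_descriptor(json.dumps(doc))
        assert any("depth cap" in i.message for i in err.value.issues)

    def test_validate_is_pure_and_ordered(self, toycalc):
        a = validate(toycalc)
        b = validate(toycalc)
        assert a == b == sorted(b)


class TestSerialize:
    def test_round_trip_structural_equality(self, toycalc):
        assert parse_descriptor(serialize_descriptor(toycalc)) == toycalc

    def test_repeated_serialization_is_byte_identical(self):
        d = parse_descriptor(MINIMAL)
        assert serialize_descriptor(d) == serialize_descriptor(d)

    def test_unknown_fields_survive_round_trip(self):
        doc = json.loads(MINIMAL)
        doc["x-custom"] = {"anything": [1, 2]}
        d = parse_descriptor(json.dumps(doc))
        out = json.loads(serialize_descriptor(d))
        assert out["x-custom"] == {"anything": [1, 2]}

    def test_random_descriptor_round_trip_200_seeds(self):
        for seed in range(200):
            d = random_descriptor(seed)
            assert parse_descriptor(serialize_descriptor(d)) == d, seed
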