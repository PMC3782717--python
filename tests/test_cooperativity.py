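"""Effect extraction, the COOP01-COOP11 rule catalogue, value parsing."""

import copy
import json

import pytest
from hypothesis import given, settings, strategies as st

from psimi_coop import (
    Attribute,
    Mechanism,
    Outcome,
    Severity,
    cdc6_full,
    effect_value_parse,
    extract_effects,
    validate,
    vignette,
)
from psimi_coop.cooperativity import (
    RULE_CODES,
    AllostericResponse,
    PreassemblyResponse,
    findings_to_jsonl,
)
from psimi_coop.errors import EffectExtractionError, ValueFormatError
from psimi_coop.fixtures import EFFECT_RECORD_IDS, mutate


class TestExtraction:
    def test_cdc6_yields_seven_effects(self, cdc6_entry, registry):
        assert len(extract_effects(cdc6_entry, registry)) == 7

    def test_effect_six_is_the_worked_example(self, cdc6_entry, registry):
        """The v-type allosteric effect of phospho-T160 on Cdc6
        phosphorylation: mechanism allostery, affected interaction 12,
        positive outcome."""
        effects = {
            e.source_interaction_id: e
            for e in extract_effects(cdc6_entry, registry)
        }
        effect6 = effects[EFFECT_RECORD_IDS[6]]
        assert effect6.mechanism is Mechanism.ALLOSTERY
        assert effect6.affected_interaction_id == 12
        assert effect6.outcome is Outcome.POSITIVE
        assert effect6.response is AllostericResponse.V_TYPE
        assert effect6.allosteric_ptm_feature_id is not None

    def test_mechanism_census(self, cdc6_entry, registry):
        effects = extract_effects(cdc6_entry, registry)
        by_mech = [e.mechanism for e in effects]
        assert by_mech.count(Mechanism.ALLOSTERY) == 5
        assert by_mech.count(Mechanism.PRE_ASSEMBLY) == 2
        assert all(e.outcome is Outcome.POSITIVE for e in effects)

    def test_interaction_without_attributes_yields_no_effect(
        self, cdc6_entry, registry
    ):
        sources = {
            e.source_interaction_id
            for e in extract_effects(cdc6_entry, registry)
        }
        assert 12 not in sources  # the affected record carries no effect

    def test_non_cooperative_attributes_ignored(self, cdc6_entry, registry):
        cdc6_entry.interactions[0].attributes.append(
            Attribute(name="comment", value="free text")
        )
        assert len(extract_effects(cdc6_entry, registry)) == 7

    def test_extraction_ignores_attribute_order(self, cdc6_entry, registry):
        reference = extract_effects(cdc6_entry, registry)
        shuffled = copy.deepcopy(cdc6_entry)
        for interaction in shuffled.interactions:
            interaction.attributes.reverse()
        assert extract_effects(shuffled, registry) == reference

    def test_strict_mode_raises_on_name_mismatch(self, registry):
        mutated = mutate(cdc6_full(), "COOP11").entries[0]
        with pytest.raises(EffectExtractionError):
            extract_effects(mutated, registry, strict=True)
        # lenient extraction resolves via the accession and carries on
        assert len(extract_effects(mutated, registry)) == 7

    def test_chey_effect_uses_ptm_not_effector(self, registry):
        (effect,) = extract_effects(
            vignette("chey_flim").entries[0], registry
        )
        assert effect.allosteric_ptm_feature_id == 30
        assert effect.allosteric_effector_id is None

    def test_skp2_effect_is_composite_binding_site(self, registry):
        (effect,) = extract_effects(
            vignette("skp2_cks1_p27").entries[0], registry
        )
        assert effect.mechanism is Mechanism.PRE_ASSEMBLY
        assert (
            effect.preassembly_response
            is PreassemblyResponse.COMPOSITE_BINDING_SITE
        )


class TestEffectValueParse:
    @pytest.mark.parametrize(
        "text,expected",
        [("10", 10.0), ("1.0", 1.0), ("2.5e3", 2500.0), ("0.04", 0.04)],
    )
    def test_accepts_positive_reals(self, text, expected):
        assert effect_value_parse(text) == expected

    @pytest.mark.parametrize("text", ["-2", "0", "ten", "", "nan", "inf"])
    def test_rejects_non_positive(self, text):
        with pytest.raises(ValueFormatError):
            effect_value_parse(text)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(
            min_value=1e-12, max_value=1e12,
            allow_nan=False, allow_infinity=False,
        )
    )
    def test_parses_any_positive_float_repr(self, value):
        assert effect_value_parse(repr(value)) == pytest.approx(value)


class TestRuleCatalogue:
    def test_fixtures_have_no_findings(self, any_fixture, registry):
        for entry in any_fixture.entries:
            assert validate(entry, registry) == []

    @pytest.mark.parametrize("code", RULE_CODES)
    def test_each_seeded_mutation_triggers_exactly_its_code(
        self, code, registry
    ):
        mutated = mutate(cdc6_full(), code).entries[0]
        findings = validate(mutated, registry)
        assert [f.code for f in findings] == [code]

    @pytest.mark.parametrize(
        "code,expected_severity",
        [("COOP03", Severity.WARNING), ("COOP05", Severity.WARNING),
         ("COOP10", Severity.WARNING), ("COOP01", Severity.ERROR),
         ("COOP02", Severity.ERROR), ("COOP09", Severity.ERROR)],
    )
    def test_severities(self, code, expected_severity, registry):
        mutated = mutate(cdc6_full(), code).entries[0]
        (finding,) = validate(mutated, registry)
        assert finding.severity is expected_severity

    def test_zero_errors_implies_extractable(self, registry):
        """Agreement between the validator and the extractor: when no rule
        reports an ERROR, extraction succeeds and every effect satisfies
        its structural invariants (enforced on construction)."""
        for code in ("COOP03", "COOP05", "COOP10"):  # warning-only variants
            entry = mutate(cdc6_full(), code).entries[0]
            errors = [
                f for f in validate(entry, registry)
                if f.severity is Severity.ERROR
            ]
            assert errors == []
            assert len(extract_effects(entry, registry)) == 7

    def test_findings_are_order_insensitive(self, registry):
        mutated = mutate(cdc6_full(), "COOP02").entries[0]
        shuffled = copy.deepcopy(mutated)
        for interaction in shuffled.interactions:
            interaction.attributes.reverse()
        assert [f.code for f in validate(shuffled, registry)] == ["COOP02"]

    def test_affected_interaction_self_reference(self, registry):
        entry = cdc6_full().entries[0]
        attr = next(
            a for a in entry.interactions[0].attributes
            if a.name_ac == "MI:1150"
        )
        attr.value = str(entry.interactions[0].id)
        assert [f.code for f in validate(entry, registry)] == ["COOP02"]

    def test_jsonl_export(self, registry):
        mutated = mutate(cdc6_full(), "COOP02").entries[0]
        lines = findings_to_jsonl(validate(mutated, registry)).splitlines()
        record = json.loads(lines[0])
        assert record["code"] == "COOP02"
        assert record["severity"] == "error"
        assert "path" in record and "message" in record
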