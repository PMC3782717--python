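"""Controlled-vocabulary registry: lookups, closure queries, OBO round trip."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from psimi_coop import builtin_registry, export_obo, import_obo
from psimi_coop.cv import (
    EXTERNAL_STUBS,
    AttributeScope,
    CvRegistry,
    CvTerm,
    ValueContract,
)
from psimi_coop.errors import (
    AmbiguityError,
    InvariantError,
    NotAnAttributeError,
    ParseError,
    UnknownTermError,
)


def _brute_force_closure(registry, accession, relations):
    """Independent oracle: naive fixpoint over the raw parent sets."""
    out = set()
    changed = True
    frontier = {accession}
    while changed:
        changed = False
        for acc in list(frontier):
            term = registry.terms[acc]
            parents = set()
            if "is_a" in relations:
                parents |= term.is_a
            if "part_of" in relations:
                parents |= term.part_of
            new = parents - out - {accession}
            if new:
                out |= new
                frontier |= new
                changed = True
    return out


class TestLookup:
    def test_cooperative_block_is_complete(self, registry):
        block = [t for t in registry if 1149 <= int(t.accession[3:]) <= 1175]
        assert len(block) == 27
        assert len(registry) == 27 + len(EXTERNAL_STUBS)

    @pytest.mark.parametrize(
        "accession,name,parents",
        [
            ("MI:1157", "allostery", {"MI:1156", "MI:0664"}),
            ("MI:1151", "participant-ref", {"MI:0668"}),
            ("MI:1149", "cooperative interaction", {"MI:0000"}),
        ],
    )
    def test_lookup_term(self, registry, accession, name, parents):
        term = registry.lookup_term(accession)
        assert term.name == name
        assert term.parents == parents

    def test_participant_ref_is_a_feature_attribute(self, registry):
        term = registry.lookup_term("MI:1151")
        assert "MI:0668" in term.is_a
        assert term.attribute_scope is AttributeScope.FEATURE_ATTRIBUTE

    def test_unknown_accession(self, registry):
        with pytest.raises(UnknownTermError):
            registry.lookup_term("MI:9999")

    @pytest.mark.parametrize(
        "name,accession",
        [
            ("affected interaction", "MI:1150"),
            ("pre-assembly", "MI:1158"),
            ("inferred by author", "MI:0363"),
        ],
    )
    def test_term_by_name(self, registry, name, accession):
        assert registry.term_by_name(name).accession == accession

    def test_term_by_name_empty_and_case(self, registry):
        with pytest.raises(UnknownTermError):
            registry.term_by_name("")
        with pytest.raises(UnknownTermError):
            registry.term_by_name("Allostery")  # strict mode is exact-case
        assert registry.term_by_name("Allostery", lenient=True).accession == "MI:1157"

    def test_lenient_ambiguity(self):
        reg = CvRegistry(
            [
                CvTerm("MI:9001", "Thing"),
                CvTerm("MI:9002", "thing"),
            ]
        )
        with pytest.raises(AmbiguityError):
            reg.term_by_name("THING", lenient=True)

    def test_duplicate_names_rejected(self):
        with pytest.raises(InvariantError):
            CvRegistry([CvTerm("MI:9001", "same"), CvTerm("MI:9002", "same")])


class TestAncestors:
    @pytest.mark.parametrize(
        "accession,relations,expected",
        [
            ("MI:1171", {"is_a"}, {"MI:1170", "MI:0664"}),
            ("MI:1149", {"is_a", "part_of"}, {"MI:0000"}),
            ("MI:1154", {"part_of"}, set()),
        ],
    )
    def test_examples(self, registry, accession, relations, expected):
        assert registry.ancestors(accession, relations) == expected

    def test_matches_brute_force_oracle(self, registry):
        for term in registry:
            for rels in ({"is_a"}, {"part_of"}, {"is_a", "part_of"}):
                assert registry.ancestors(term.accession, rels) == (
                    _brute_force_closure(registry, term.accession, rels)
                ), (term.accession, rels)

    def test_closure_is_idempotent(self, registry):
        for term in registry:
            anc = registry.ancestors(term.accession)
            for parent in anc:
                assert registry.ancestors(parent) <= anc | {parent}

    def test_unknown_accession(self, registry):
        with pytest.raises(UnknownTermError):
            registry.ancestors("MI:9999")

    def test_every_block_term_reaches_a_root(self, registry):
        """Each cooperative term connects to the cooperative-interaction
        root or to a pre-existing external term."""
        roots = set(EXTERNAL_STUBS) | {"MI:1149"}
        for term in registry:
            if term.accession in EXTERNAL_STUBS:
                continue
            assert registry.ancestors(term.accession) & roots, term.accession


#: The published attribute-name/value convention: what each term requires.
TABLE_CONTRACTS = {
    "MI:1150": ValueContract.INTERACTION_ID,
    "MI:1152": ValueContract.FOLD_CHANGE,
    "MI:1154": ValueContract.NO_VALUE,
    "MI:1155": ValueContract.NO_VALUE,
    "MI:1157": ValueContract.NO_VALUE,
    "MI:1158": ValueContract.NO_VALUE,
    "MI:1159": ValueContract.PARTICIPANT_ID,
    "MI:1160": ValueContract.PARTICIPANT_ID,
    "MI:1162": ValueContract.NO_VALUE,
    "MI:1163": ValueContract.NO_VALUE,
    "MI:1165": ValueContract.NO_VALUE,
    "MI:1166": ValueContract.NO_VALUE,
    "MI:1168": ValueContract.NO_VALUE,
    "MI:1169": ValueContract.NO_VALUE,
    "MI:1171": ValueContract.NO_VALUE,
    "MI:1172": ValueContract.NO_VALUE,
    "MI:1173": ValueContract.NO_VALUE,
    "MI:1174": ValueContract.NO_VALUE,
    "MI:1175": ValueContract.FEATURE_ID,
    "MI:1151": ValueContract.PARTICIPANT_ID,
}


class TestValueRequirement:
    def test_contract_table(self, registry):
        for accession, contract in TABLE_CONTRACTS.items():
            assert registry.value_requirement(accession) is contract, accession

    def test_grouping_terms_are_not_attributes(self, registry):
        for accession in ("MI:1149", "MI:1153", "MI:1156", "MI:1161",
                          "MI:1164", "MI:1167", "MI:1170"):
            with pytest.raises(NotAnAttributeError):
                registry.value_requirement(accession)


class TestObo:
    def test_round_trip_identity(self, registry):
        assert import_obo(export_obo(registry)) == registry

    def test_export_contains_root_stanza(self, registry):
        assert "id: MI:1149" in export_obo(registry)

    def test_empty_registry_exports_header_only(self):
        text = export_obo(CvRegistry([]))
        assert "format-version" in text and "[Term]" not in text

    def test_obonet_agrees_on_structure(self, registry):
        """Cross-check the OBO text against an independent OBO reader."""
        obonet = pytest.importorskip("obonet")
        graph = obonet.read_obo(io.StringIO(export_obo(registry)))
        assert set(graph.nodes) == set(registry.terms)
        assert graph.nodes["MI:1157"]["name"] == "allostery"
        # is_a edge recorded by obonet as term -> parent
        assert ("MI:1171", "MI:1170", "is_a") in graph.edges(keys=True)

    def test_missing_id_is_parse_error(self):
        with pytest.raises(ParseError):
            import_obo("[Term]\nname: orphan\n")

    def test_duplicate_accession_is_parse_error(self):
        text = (
            "[Term]\nid: MI:9001\nname: a\n\n"
            "[Term]\nid: MI:9001\nname: b\n"
        )
        with pytest.raises(ParseError) as excinfo:
            import_obo(text)
        assert excinfo.value.line == 5

    def test_unknown_relationship_types_ignored(self):
        text = (
            "[Term]\nid: MI:9001\nname: a\n"
            "relationship: regulates MI:9002 ! b\n\n"
            "[Term]\nid: MI:9002\nname: b\n"
        )
        reg = import_obo(text)
        assert reg.ancestors("MI:9001") == set()


@settings(derandomize=True, max_examples=25)
@given(
    st.lists(
        st.integers(min_value=9000, max_value=9999),
        min_size=1, max_size=8, unique=True,
    ),
    st.randoms(use_true_random=False),
)
def test_obo_round_trip_on_random_registries(numbers, rng):
    """import_obo(export_obo(R)) == R for arbitrary small DAG registries."""
    terms = []
    for i, n in enumerate(numbers):
        parents = [f"MI:{m:04d}" for m in rng.sample(numbers[:i], k=min(i, 2))]
        terms.append(
            CvTerm(
                accession=f"MI:{n:04d}",
                name=f"term {n}",
                definition=f'def with "quotes" #{n}',
                is_a=frozenset(parents[:1]),
                part_of=frozenset(parents[1:]),
                value_contract=rng.choice(list(ValueContract)),
                attribute_scope=rng.choice(list(AttributeScope)),
            )
        )
    registry = CvRegistry(terms)
    assert import_obo(export_obo(registry)) == registry
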