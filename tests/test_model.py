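"""Data model: invariants, reference resolution, id-based navigation."""

import copy

import pytest

from psimi_coop import (
    Attribute,
    CvRef,
    Entry,
    EntrySet,
    Feature,
    Interaction,
    Participant,
    find_feature,
    find_participant,
    resolve_references,
)
from psimi_coop.errors import InvariantError, UnknownIdError

_TYPE = CvRef("MI:0407", "direct interaction")


def _participant(pid, interactor_ref=None, interaction_ref=None, **kw):
    return Participant(
        pid, interactor_ref=interactor_ref, interaction_ref=interaction_ref,
        **kw,
    )


class TestInvariants:
    def test_participant_needs_exactly_one_reference(self):
        with pytest.raises(InvariantError):
            Participant(1)
        with pytest.raises(InvariantError):
            Participant(1, interactor_ref=2, interaction_ref=3)

    def test_feature_range_ordering(self):
        Feature(1, CvRef("MI:0170", "phosphorylated residue"),
                ranges=[(57, 57), None])
        with pytest.raises(InvariantError):
            Feature(1, CvRef("MI:0170", "phosphorylated residue"),
                    ranges=[(5, 3)])
        with pytest.raises(InvariantError):
            Feature(1, CvRef("MI:0170", "phosphorylated residue"),
                    ranges=[(0, 3)])

    def test_interaction_needs_participants(self):
        with pytest.raises(InvariantError):
            Interaction(1, "x", participants=[])

    @pytest.mark.parametrize("bad_id", [0, -3, True])
    def test_ids_are_positive_integers(self, bad_id):
        with pytest.raises(InvariantError):
            Interaction(bad_id, "x", participants=[_participant(1, 2)])

    def test_duplicate_ids_per_class_rejected(self):
        inter = Interaction(1, "a", participants=[_participant(5, 1)])
        with pytest.raises(InvariantError):
            Entry(interactions=[inter, copy.deepcopy(inter)])

    def test_cross_class_id_collisions_are_legal(self, cdc6_entry):
        # the worked example reuses small integers across element classes
        ids = {i.id for i in cdc6_entry.interactors}
        assert ids & {i.id for i in cdc6_entry.interactions} == set()
        # participant 13 coexists with interactor/interaction ids ~ 1..12
        assert find_participant(cdc6_entry, 5, 13)

    def test_attribute_name_ac_pattern(self):
        with pytest.raises(InvariantError):
            Attribute(name="x", name_ac="MI:12")
        with pytest.raises(InvariantError):
            Attribute(name="")

    def test_entry_set_declares_254(self):
        entry = Entry()
        with pytest.raises(InvariantError):
            EntrySet(entries=[entry], minor_version=3)
        with pytest.raises(InvariantError):
            EntrySet(entries=[])


class TestResolveReferences:
    def test_fixtures_are_closed(self, any_fixture):
        for entry in any_fixture.entries:
            assert resolve_references(entry).ok

    def test_dangling_interactor_ref(self):
        entry = Entry(
            interactions=[
                Interaction(1, "x", participants=[_participant(2, 99)])
            ]
        )
        report = resolve_references(entry)
        assert len(report.dangling) == 1
        path, kind, ref = report.dangling[0]
        assert kind == "interactorRef" and ref == 99
        assert "interaction[1]" in path

    def test_self_referencing_participant(self):
        entry = Entry(
            interactions=[
                Interaction(
                    1, "x", participants=[_participant(2, interaction_ref=1)]
                )
            ]
        )
        report = resolve_references(entry)
        assert [kind for _, kind, _ in report.dangling] == [
            "interactionRef(cycle)"
        ]

    def test_mutual_consumption_cycle_detected(self):
        entry = Entry(
            interactions=[
                Interaction(1, "a", participants=[_participant(3, interaction_ref=2)]),
                Interaction(2, "b", participants=[_participant(4, interaction_ref=1)]),
            ]
        )
        report = resolve_references(entry)
        assert any(kind == "interactionRef(cycle)" for _, kind, _ in report.dangling)

    def test_single_seeded_break_yields_single_record(self, cdc6_entry):
        broken = copy.deepcopy(cdc6_entry)
        broken.interactions[-1].participants[-1].interactor_ref = 999
        report = resolve_references(broken)
        assert len(report.dangling) == 1
        assert report.dangling[0][2] == 999


class TestNavigation:
    def test_find_participant_cdk2(self, cdc6_entry):
        participant = find_participant(cdc6_entry, 5, 13)
        assert cdc6_entry.interactor(participant.interactor_ref).short_label == "cdk2"

    @pytest.mark.parametrize("interaction_id,participant_id", [(5, 999), (999, 13)])
    def test_find_participant_unknown(self, cdc6_entry, interaction_id, participant_id):
        with pytest.raises(UnknownIdError):
            find_participant(cdc6_entry, interaction_id, participant_id)

    def test_find_feature_phospho_t160(self, cdc6_entry):
        interaction, participant, feature = find_feature(cdc6_entry, 30)
        assert feature.feature_type.accession == "MI:0170"
        assert feature.ranges == [(160, 160)]
        assert participant.interaction_ref == 5
        assert interaction.short_label == "CyclinA_Cdk2-Cdk7"

    def test_find_feature_unknown(self, cdc6_entry):
        with pytest.raises(UnknownIdError):
            find_feature(cdc6_entry, 0)
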