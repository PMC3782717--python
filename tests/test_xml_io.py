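"""XML reader/writer: round trips, schema validity, extras passthrough."""

import pytest
from lxml import etree

from psimi_coop import (
    cdc6_full,
    read_entry_set,
    validate_against_schema,
    write_entry_set,
)
from psimi_coop.errors import FormatError, RefError
from psimi_coop.model import Entry, EntrySet, Interaction, Participant
from psimi_coop.xml_io import MIF_NS


class TestRoundTrip:
    def test_read_write_identity(self, any_fixture):
        assert read_entry_set(write_entry_set(any_fixture)) == any_fixture

    def test_twice_written_is_byte_stable(self, any_fixture):
        once = write_entry_set(any_fixture)
        assert write_entry_set(read_entry_set(once)) == once

    def test_root_declares_254(self, cdc6):
        root = etree.fromstring(write_entry_set(cdc6).encode())
        assert root.get("level") == "2"
        assert root.get("version") == "5"
        assert root.get("minorVersion") == "4"
        assert etree.QName(root).namespace == MIF_NS

    def test_entry_children_in_schema_order(self, cdc6):
        root = etree.fromstring(write_entry_set(cdc6).encode())
        entry = root[0]
        tags = [etree.QName(c).localname for c in entry]
        order = ["source", "availabilityList", "experimentList",
                 "interactorList", "interactionList", "attributeList"]
        assert tags == sorted(tags, key=order.index)

    def test_affected_interaction_attribute_serialized(self, cdc6):
        """The effect on the Cdk7-phosphorylation record points at the
        affected interaction by id (12)."""
        root = etree.fromstring(write_entry_set(cdc6).encode())
        hits = root.findall(f".//{{{MIF_NS}}}attribute[@nameAc='MI:1150']")
        assert "12" in {a.text for a in hits}

    def test_valueless_attribute_reads_as_none(self, cdc6):
        entry_set = read_entry_set(write_entry_set(cdc6))
        allostery_attrs = [
            a
            for i in entry_set.entries[0].interactions
            for a in i.attributes
            if a.name_ac == "MI:1157"
        ]
        assert allostery_attrs and all(a.value is None for a in allostery_attrs)


class TestReaderErrors:
    def test_wrong_root_element(self):
        with pytest.raises(FormatError):
            read_entry_set(f'<interactionList xmlns="{MIF_NS}"/>')

    def test_wrong_namespace(self):
        with pytest.raises(FormatError):
            read_entry_set('<entrySet xmlns="urn:other" level="2" version="5" minorVersion="4"/>')

    def test_non_integer_id_reports_path(self, cdc6):
        text = write_entry_set(cdc6).replace('interactor id="1"', 'interactor id="one"')
        with pytest.raises(FormatError, match="interactor"):
            read_entry_set(text)

    def test_ill_formed_xml(self):
        with pytest.raises(FormatError):
            read_entry_set("<entrySet>")


class TestWriterErrors:
    def test_dangling_reference_refused(self):
        entry = Entry(
            interactions=[
                Interaction(1, "x", participants=[Participant(2, interactor_ref=99)])
            ]
        )
        with pytest.raises(RefError, match="interactorRef=99"):
            write_entry_set(EntrySet(entries=[entry]))


class TestSchemaValidation:
    def test_fixture_documents_are_schema_valid(self, any_fixture):
        assert validate_against_schema(write_entry_set(any_fixture)) == []

    def test_missing_participant_list_is_flagged(self, cdc6):
        root = etree.fromstring(write_entry_set(cdc6).encode())
        interaction = root.find(f".//{{{MIF_NS}}}interaction")
        interaction.remove(interaction.find(f"{{{MIF_NS}}}participantList"))
        findings = validate_against_schema(etree.tostring(root))
        assert findings and any("participantList" in f for f in findings)

    def test_non_integer_id_is_flagged(self, cdc6):
        text = write_entry_set(cdc6).replace('interaction id="5"', 'interaction id="five"')
        assert validate_against_schema(text)


class TestExpandedFormAndExtras:
    def test_inline_interactor_lifted_to_list(self):
        text = f"""<?xml version="1.0"?>
<entrySet xmlns="{MIF_NS}" level="2" version="5" minorVersion="4">
  <entry>
    <interactionList>
      <interaction id="1">
        <names><shortLabel>pair</shortLabel></names>
        <participantList>
          <participant id="2">
            <interactor id="7">
              <names><shortLabel>inline_prot</shortLabel></names>
              <interactorType>
                <names><shortLabel>protein</shortLabel></names>
                <xref><primaryRef db="psi-mi" id="MI:0326"/></xref>
              </interactorType>
            </interactor>
          </participant>
        </participantList>
      </interaction>
    </interactionList>
  </entry>
</entrySet>"""
        entry = read_entry_set(text).entries[0]
        assert [i.short_label for i in entry.interactors] == ["inline_prot"]
        assert entry.interactions[0].participants[0].interactor_ref == 7

    def test_availability_list_passes_through_verbatim(self, cdc6):
        text = write_entry_set(cdc6)
        payload = (
            f'<availabilityList xmlns="{MIF_NS}">'
            '<availability id="1">free for academic use</availability>'
            "</availabilityList>"
        )
        with_avail = text.replace("<experimentList>", payload + "<experimentList>", 1)
        entry_set = read_entry_set(with_avail)
        assert "availabilityList" in entry_set.entries[0].extras
        rewritten = write_entry_set(entry_set)
        assert "free for academic use" in rewritten
        # and the extra survives another full cycle unchanged
        assert read_entry_set(rewritten) == entry_set
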