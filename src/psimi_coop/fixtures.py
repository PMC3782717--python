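"""Deterministic worked-example entries and seeded-violation variants.

The flagship fixture reproduces the ordered, cooperative build-up of the
active Cyclin A-Cdk2 complex and its substrate Cdc6:

* Interaction A ("CyclinA-Cdk2", record id 5) — Cyclin A binds Cdk2.  The
  Cdk2 participant of this record has id 13.
* Interaction B ("CyclinA_Cdk2-Cdk7") — Cdk7 (interactor id 3)
  phosphorylates T160 of Cdk2 *in the pre-formed complex*: one participant
  is Cdk7 by interactor reference, the other references interaction 5 as a
  pre-formed complex and carries the phospho-T160 feature, whose
  participant-ref attribute (value 13) pins the PTM onto the Cdk2 subunit.
* Interaction C ("CyclinA_pCdk2-Cdc6", record id 12) — the phosphorylated
  complex recruits and phosphorylates Cdc6.

Seven cooperative effects are annotated, one per record (records are
repeated because an attribute list holds a single effect):

1. A pre-organizes a bipartite Cdc6 binding site          (pre-assembly,
   composite binding site formation, -> C)
2. A aligns the Cdk2 active site, promoting catalysis     (allostery,
   v-type, -> C)
3. A moves the T loop, unblocking substrate access        (allostery,
   k-type, -> C)
4. A exposes T160 for phosphorylation by Cdk7             (allostery,
   k-type, -> B)
5. phospho-T160 opens the P+1 substrate pocket            (allostery,
   k-type, -> C)
6. phospho-T160 stabilizes the transition state           (allostery,
   v-type, -> C)
7. phospho-T160 hydrogen-bonds the substrate P+3 lysine   (pre-assembly,
   altered physicochemical compatibility, -> C)

All effects are positive.  Record B carries the external DIP record
cross-reference for the primary interaction evidence; experiments use the
inferred-by-author / inferred-by-curator detection methods.

All bibliographic identifiers on fixture experiments are synthetic
placeholders; UniProt/ChEBI accessions on interactors are decorative
metadata and never fetched.
"""

from __future__ import annotations

import copy

from .cv import CvRegistry, builtin_registry
from .errors import UsageError
from .model import (
    Attribute,
    CvRef,
    Entry,
    EntrySet,
    ExperimentDescription,
    Feature,
    Interaction,
    Interactor,
    Participant,
    Xref,
)

__all__ = ["cdc6_full", "vignette", "mutate", "EFFECT_RECORD_IDS", "VIGNETTES"]

_PROTEIN = CvRef("MI:0326", "protein")
_SMALL_MOLECULE = CvRef("MI:0328", "small molecule")
_PHOSPHO = CvRef("MI:0170", "phosphorylated residue")
_DIRECT = CvRef("MI:0407", "direct interaction")
_PHOSPHORYLATION = CvRef("MI:0217", "phosphorylation reaction")
_BY_AUTHOR = CvRef("MI:0363", "inferred by author")
_BY_CURATOR = CvRef("MI:0364", "inferred by curator")

#: Fig-style effect numbering -> interaction record id in ``cdc6_full``.
EFFECT_RECORD_IDS = {1: 5, 2: 7, 3: 8, 4: 9, 5: 6, 6: 10, 7: 11}

_registry = builtin_registry()


def _attr(accession: str, value: str | None = None) -> Attribute:
    term = _registry.lookup_term(accession)
    return Attribute(name=term.name, name_ac=accession, value=value)


def _bibref(placeholder: str) -> Xref:
    # synthetic placeholder pubmed ids; see module docstring
    return Xref(db="pubmed", id=placeholder)


def _experiments() -> list[ExperimentDescription]:
    return [
        ExperimentDescription(
            id=1, bibref=_bibref("9000001"),
            interaction_detection_method=_BY_AUTHOR,
        ),
        ExperimentDescription(
            id=2, bibref=_bibref("9000002"),
            interaction_detection_method=_BY_CURATOR,
        ),
    ]


def _phospho_t160(feature_id: int) -> Feature:
    return Feature(
        id=feature_id,
        feature_type=_PHOSPHO,
        ranges=[(160, 160)],
        attributes=[_attr("MI:1151", "13")],
    )


def cdc6_full() -> EntrySet:
    """The full Cdc6 worked example: 4 interactors, 8 interaction records
    (3 merged binding events), 7 cooperative effects."""
    interactors = [
        Interactor(1, "cyclin_a", _PROTEIN, full_name="Cyclin-A2",
                   organism_taxid=9606, xref=Xref("uniprotkb", "P20248")),
        Interactor(2, "cdk2", _PROTEIN, full_name="Cyclin-dependent kinase 2",
                   organism_taxid=9606, xref=Xref("uniprotkb", "P24941")),
        Interactor(3, "cdk7", _PROTEIN, full_name="Cyclin-dependent kinase 7",
                   organism_taxid=9606, xref=Xref("uniprotkb", "P50613")),
        Interactor(4, "cdc6", _PROTEIN,
                   full_name="Cell division control protein 6 homolog",
                   organism_taxid=9606, xref=Xref("uniprotkb", "Q99741")),
    ]

    def record_a(rid, pids, attrs, exp):
        cyclin_pid, cdk2_pid = pids
        return Interaction(
            id=rid, short_label="CyclinA-Cdk2",
            experiment_refs=[exp],
            participants=[
                Participant(cyclin_pid, interactor_ref=1),
                Participant(cdk2_pid, interactor_ref=2),
            ],
            interaction_type=_DIRECT,
            attributes=attrs,
        )

    def record_b(rid, cdk7_pid, complex_pid, feature_id, attrs, exp,
                 xref=None):
        return Interaction(
            id=rid, short_label="CyclinA_Cdk2-Cdk7",
            xref=xref,
            experiment_refs=[exp],
            participants=[
                Participant(cdk7_pid, interactor_ref=3),
                Participant(
                    complex_pid, interaction_ref=5,
                    features=[_phospho_t160(feature_id)],
                ),
            ],
            interaction_type=_PHOSPHORYLATION,
            attributes=attrs,
        )

    interactions = [
        # effect 1: A pre-organizes the bipartite Cdc6 binding site
        record_a(5, (10, 13), [
            _attr("MI:1158"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1171"),
        ], exp=2),
        # effect 5: phospho-T160 opens the P+1 substrate pocket
        record_b(6, 14, 15, 30, [
            _attr("MI:1157"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1162"), _attr("MI:1159", "15"), _attr("MI:1175", "30"),
        ], exp=1, xref=Xref("dip", "DIP57013E")),
        # effect 2: A aligns the active site, promoting catalysis
        record_a(7, (16, 17), [
            _attr("MI:1157"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1163"), _attr("MI:1165"),
            _attr("MI:1159", "17"), _attr("MI:1160", "16"),
        ], exp=2),
        # effect 3: A repositions the T loop, unblocking substrate access
        record_a(8, (18, 19), [
            _attr("MI:1157"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1162"), _attr("MI:1165"),
            _attr("MI:1159", "19"), _attr("MI:1160", "18"),
        ], exp=2),
        # effect 4: A exposes T160, enabling phosphorylation by Cdk7
        record_a(9, (21, 22), [
            _attr("MI:1157"), _attr("MI:1150", "6"), _attr("MI:1154"),
            _attr("MI:1162"),
            _attr("MI:1159", "22"), _attr("MI:1160", "21"),
        ], exp=2),
        # effect 6: phospho-T160 stabilizes the transition state
        record_b(10, 23, 24, 31, [
            _attr("MI:1157"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1163"), _attr("MI:1159", "24"), _attr("MI:1175", "31"),
        ], exp=1),
        # effect 7: phospho-T160 hydrogen-bonds the P+3 lysine of Cdc6
        record_b(11, 25, 26, 32, [
            _attr("MI:1158"), _attr("MI:1150", "12"), _attr("MI:1154"),
            _attr("MI:1172"),
        ], exp=2),
        # interaction C: the phosphorylated complex recruits Cdc6
        Interaction(
            id=12, short_label="CyclinA_pCdk2-Cdc6",
            experiment_refs=[2],
            participants=[
                Participant(27, interaction_ref=6),
                Participant(28, interactor_ref=4),
            ],
            interaction_type=_PHOSPHORYLATION,
        ),
    ]

    entry = Entry(
        source="psimi-coop fixtures",
        experiments=_experiments(),
        interactors=interactors,
        interactions=interactions,
    )
    return EntrySet(entries=[entry])


# ---------------------------------------------------------------------------
# vignettes
# ---------------------------------------------------------------------------


def _chey_flim() -> EntrySet:
    """Allosteric control by PTM: phospho-D57 stabilizes the active CheY
    conformer, raising its affinity for the flagellar motor protein FliM."""
    entry = Entry(
        source="psimi-coop fixtures",
        experiments=[
            ExperimentDescription(
                id=1, bibref=_bibref("9000003"),
                interaction_detection_method=_BY_AUTHOR,
            )
        ],
        interactors=[
            Interactor(1, "chey", _PROTEIN, organism_taxid=83333,
                       xref=Xref("uniprotkb", "P0AE67")),
            Interactor(2, "flim", _PROTEIN, organism_taxid=83333,
                       xref=Xref("uniprotkb", "P06974")),
        ],
        interactions=[
            Interaction(
                id=3, short_label="CheY-phospho",
                experiment_refs=[1],
                participants=[
                    Participant(
                        10, interactor_ref=1,
                        features=[
                            Feature(30, _PHOSPHO, ranges=[(57, 57)])
                        ],
                    )
                ],
                interaction_type=_PHOSPHORYLATION,
                attributes=[
                    _attr("MI:1157"), _attr("MI:1150", "4"),
                    _attr("MI:1154"), _attr("MI:1168"), _attr("MI:1162"),
                    _attr("MI:1165"),
                    _attr("MI:1159", "10"), _attr("MI:1175", "30"),
                ],
            ),
            Interaction(
                id=4, short_label="CheY-FliM",
                experiment_refs=[1],
                participants=[
                    Participant(11, interactor_ref=1),
                    Participant(12, interactor_ref=2),
                ],
                interaction_type=_DIRECT,
            ),
        ],
    )
    return EntrySet(entries=[entry])


def _skp2_cks1_p27() -> EntrySet:
    """Pre-assembly: Skp2 and Cks1 form a continuous composite binding site
    required for recruiting the Cdk inhibitor p27."""
    entry = Entry(
        source="psimi-coop fixtures",
        experiments=[
            ExperimentDescription(
                id=1, bibref=_bibref("9000004"),
                interaction_detection_method=_BY_CURATOR,
            )
        ],
        interactors=[
            Interactor(1, "skp2", _PROTEIN, organism_taxid=9606,
                       xref=Xref("uniprotkb", "Q13309")),
            Interactor(2, "cks1", _PROTEIN, organism_taxid=9606,
                       xref=Xref("uniprotkb", "P61024")),
            Interactor(3, "p27", _PROTEIN, organism_taxid=9606,
                       xref=Xref("uniprotkb", "P46527")),
        ],
        interactions=[
            Interaction(
                id=4, short_label="Skp2-Cks1",
                experiment_refs=[1],
                participants=[
                    Participant(10, interactor_ref=1),
                    Participant(11, interactor_ref=2),
                ],
                interaction_type=_DIRECT,
                attributes=[
                    _attr("MI:1158"), _attr("MI:1150", "5"),
                    _attr("MI:1154"), _attr("MI:1171"),
                ],
            ),
            Interaction(
                id=5, short_label="Skp2_Cks1-p27",
                experiment_refs=[1],
                participants=[
                    Participant(12, interaction_ref=4),
                    Participant(13, interactor_ref=3),
                ],
                interaction_type=_DIRECT,
            ),
        ],
    )
    return EntrySet(entries=[entry])


def _plcg1_lat() -> EntrySet:
    """Configurational pre-organization: the SH2 and PH domain interactions
    of PLCg1 (with phospho-LAT and membrane phosphoinositides) mutually
    stabilize each other — a cooperative two-cycle."""
    entry = Entry(
        source="psimi-coop fixtures",
        experiments=[
            ExperimentDescription(
                id=1, bibref=_bibref("9000005"),
                interaction_detection_method=_BY_AUTHOR,
            )
        ],
        interactors=[
            Interactor(1, "plcg1", _PROTEIN, organism_taxid=9606,
                       xref=Xref("uniprotkb", "P19174")),
            Interactor(2, "lat", _PROTEIN, organism_taxid=9606,
                       xref=Xref("uniprotkb", "O43561")),
            Interactor(3, "pip3", _SMALL_MOLECULE,
                       xref=Xref("chebi", "CHEBI:16618")),
        ],
        interactions=[
            Interaction(
                id=4, short_label="PLCg1_SH2-LAT",
                experiment_refs=[1],
                participants=[
                    Participant(10, interactor_ref=1),
                    Participant(11, interactor_ref=2),
                ],
                interaction_type=_DIRECT,
                attributes=[
                    _attr("MI:1158"), _attr("MI:1150", "5"),
                    _attr("MI:1154"), _attr("MI:1174"),
                ],
            ),
            Interaction(
                id=5, short_label="PLCg1_PH-PIP3",
                experiment_refs=[1],
                participants=[
                    Participant(12, interactor_ref=1),
                    Participant(13, interactor_ref=3),
                ],
                interaction_type=_DIRECT,
                attributes=[
                    _attr("MI:1158"), _attr("MI:1150", "4"),
                    _attr("MI:1154"), _attr("MI:1174"),
                ],
            ),
        ],
    )
    return EntrySet(entries=[entry])


VIGNETTES = {
    "chey_flim": _chey_flim,
    "skp2_cks1_p27": _skp2_cks1_p27,
    "plcg1_lat": _plcg1_lat,
}


def vignette(name: str) -> EntrySet:
    """One of the small mechanism vignettes: ``chey_flim`` (allosteric
    PTM), ``skp2_cks1_p27`` (composite binding site) or ``plcg1_lat``
    (configurational pre-organization, cooperative cycle)."""
    try:
        return VIGNETTES[name]()
    except KeyError:
        raise UsageError(
            f"unknown vignette {name!r}; choose from {sorted(VIGNETTES)}"
        ) from None


# ---------------------------------------------------------------------------
# seeded violations
# ---------------------------------------------------------------------------


def _first_with_attr(entry: Entry, accession: str) -> tuple:
    for interaction in entry.interactions:
        for attr in interaction.attributes:
            if attr.name_ac == accession:
                return interaction, attr
    raise UsageError(f"fixture has no attribute with nameAc {accession}")


def mutate(entry_set: EntrySet, code: str, registry: CvRegistry | None = None) -> EntrySet:
    """A minimally altered deep copy guaranteed to trigger exactly the
    named rule code (and no other ERROR) under
    :func:`~psimi_coop.cooperativity.validate`."""
    registry = registry or _registry
    mutated = copy.deepcopy(entry_set)
    entry = mutated.entries[0]

    def term_attr(ac, value=None):
        term = registry.lookup_term(ac)
        return Attribute(name=term.name, name_ac=ac, value=value)

    if code == "COOP01":
        interaction, attr = _first_with_attr(entry, "MI:1158")
        interaction.attributes.append(term_attr("MI:1157"))
    elif code == "COOP02":
        _, attr = _first_with_attr(entry, "MI:1150")
        attr.value = "999"
    elif code == "COOP03":
        interaction, attr = _first_with_attr(entry, "MI:1154")
        interaction.attributes.remove(attr)
    elif code == "COOP04":
        interaction, _ = _first_with_attr(entry, "MI:1158")
        interaction.attributes.append(term_attr("MI:1152", "-2"))
    elif code == "COOP05":
        _, attr = _first_with_attr(entry, "MI:1158")
        attr.value = "yes"
    elif code == "COOP06":
        _, attr = _first_with_attr(entry, "MI:1159")
        attr.value = "999"
    elif code == "COOP07":
        interaction, _ = _first_with_attr(entry, "MI:1158")
        interaction.attributes.append(term_attr("MI:1162"))
    elif code == "COOP08":
        interaction, attr = _first_with_attr(entry, "MI:1162")
        interaction.attributes.append(term_attr("MI:1163"))
    elif code == "COOP09":
        for _, participant in [
            (i, p) for i in entry.interactions for p in i.participants
        ]:
            hit = next(
                (
                    a
                    for f in participant.features
                    for a in f.attributes
                    if a.name_ac == "MI:1151"
                ),
                None,
            )
            if hit is not None:
                hit.value = "999"
                break
        else:
            raise UsageError("fixture has no participant-ref feature attribute")
    elif code == "COOP10":
        entry.experiments.append(
            ExperimentDescription(
                id=99, bibref=_bibref("9000099"),
                interaction_detection_method=CvRef(
                    "MI:0045", "experimental interaction detection"
                ),
            )
        )
        interaction, _ = _first_with_attr(entry, "MI:1158")
        interaction.experiment_refs = [99]
    elif code == "COOP11":
        _, attr = _first_with_attr(entry, "MI:1157")
        attr.name = "allosterie"
    else:
        raise UsageError(f"unknown rule code {code!r}")
    return mutated
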