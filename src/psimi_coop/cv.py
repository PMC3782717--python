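"""Embedded controlled vocabulary for cooperative molecular interactions.

The PSI-MI controlled vocabulary (CV) identifies curation concepts by stable
accessions of the form ``MI:NNNN``.  Cooperative binding — distinct binding
events (including covalent modifications) influencing one another positively
or negatively — is annotated with a dedicated block of 27 terms, MI:1149
through MI:1175, hanging off the root term MI:1149 "cooperative interaction".
Most of these double as *interaction attribute names* (children of MI:0664),
so that a curator can attach them as ``<attribute>`` names inside an
interaction record; one (participant-ref, MI:1151) is a *feature attribute
name* (child of MI:0668) used to pin a feature onto one subunit of a
referenced pre-formed complex.

This module embeds that block together with stub records for the handful of
pre-existing PSI-MI terms the relations point at, so transitive-closure
queries terminate without loading the full PSI-MI CV.  It also reads and
writes the vocabulary as OBO 1.2 flat-file ``[Term]`` stanzas.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import (
    AmbiguityError,
    InvariantError,
    NotAnAttributeError,
    ParseError,
    UnknownTermError,
)

__all__ = [
    "ValueContract",
    "AttributeScope",
    "CvTerm",
    "CvRegistry",
    "builtin_registry",
    "export_obo",
    "import_obo",
    "EXTERNAL_STUBS",
    "MI_PATTERN",
]

MI_PATTERN = re.compile(r"^MI:\d{4}$")

#: Pre-existing PSI-MI terms referenced by the cooperative-interaction block.
#: Embedded as stubs (name only) so closure queries are self-contained.
EXTERNAL_STUBS = {
    "MI:0000": "molecular interaction",
    "MI:0252": "biological feature",
    "MI:0363": "inferred by author",
    "MI:0364": "inferred by curator",
    "MI:0500": "biological role",
    "MI:0664": "interaction attribute name",
    "MI:0668": "feature attribute name",
}


class ValueContract(enum.Enum):
    """What an attribute named by a term must carry as its value."""

    NO_VALUE = "none"
    INTERACTION_ID = "interaction id"
    PARTICIPANT_ID = "participant id"
    FEATURE_ID = "feature id"
    FOLD_CHANGE = "fold change"


class AttributeScope(enum.Enum):
    INTERACTION_ATTRIBUTE = "interaction attribute"
    FEATURE_ATTRIBUTE = "feature attribute"
    NOT_AN_ATTRIBUTE = "not an attribute"


@dataclass(frozen=True)
class CvTerm:
    """One controlled-vocabulary term."""

    accession: str
    name: str
    definition: str = ""
    is_a: frozenset[str] = frozenset()
    part_of: frozenset[str] = frozenset()
    value_contract: ValueContract = ValueContract.NO_VALUE
    attribute_scope: AttributeScope = AttributeScope.NOT_AN_ATTRIBUTE

    def __post_init__(self):
        if not MI_PATTERN.match(self.accession):
            raise InvariantError(
                f"accession {self.accession!r} does not match MI:NNNN"
            )
        if not self.name:
            raise InvariantError(f"term {self.accession} has an empty name")
        # normalise to frozensets so terms are hashable/comparable
        object.__setattr__(self, "is_a", frozenset(self.is_a))
        object.__setattr__(self, "part_of", frozenset(self.part_of))

    @property
    def parents(self) -> frozenset[str]:
        return self.is_a | self.part_of


class CvRegistry:
    """A closed set of CV terms supporting lookup and closure queries.

    Every parent accession referenced by a member term must itself be a
    member (the builtin registry guarantees this via the external stubs).
    """

    def __init__(self, terms: Iterable[CvTerm]):
        self._terms: dict[str, CvTerm] = {}
        self._by_name: dict[str, str] = {}
        for term in terms:
            if term.accession in self._terms:
                raise InvariantError(f"duplicate accession {term.accession}")
            if term.name in self._by_name:
                raise InvariantError(f"duplicate term name {term.name!r}")
            self._terms[term.accession] = term
            self._by_name[term.name] = term.accession
        for term in self._terms.values():
            for parent in term.parents:
                if parent not in self._terms:
                    raise InvariantError(
                        f"{term.accession} references unknown parent {parent}"
                    )

    # -- basic queries ----------------------------------------------------

    def __contains__(self, accession: str) -> bool:
        return accession in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(sorted(self._terms.values(), key=lambda t: t.accession))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CvRegistry):
            return NotImplemented
        return self._terms == other._terms

    @property
    def terms(self) -> Mapping[str, CvTerm]:
        return dict(self._terms)

    def lookup_term(self, accession: str) -> CvTerm:
        """Return the term with this accession.

        Raises :class:`UnknownTermError` for accessions outside the registry.
        """
        try:
            return self._terms[accession]
        except KeyError:
            raise UnknownTermError(f"unknown CV accession {accession!r}") from None

    def term_by_name(self, name: str, lenient: bool = False) -> CvTerm:
        """Exact-name lookup; case-insensitive when ``lenient`` is true."""
        accession = self._by_name.get(name)
        if accession is not None:
            return self._terms[accession]
        if lenient:
            hits = [
                acc for nm, acc in self._by_name.items()
                if nm.lower() == name.lower()
            ]
            if len(hits) > 1:
                raise AmbiguityError(
                    f"name {name!r} matches several terms case-insensitively: "
                    + ", ".join(sorted(hits))
                )
            if hits:
                return self._terms[hits[0]]
        raise UnknownTermError(f"no CV term named {name!r}")

    def ancestors(
        self, accession: str, relations: Iterable[str] = ("is_a", "part_of")
    ) -> set[str]:
        """Transitive closure of the selected parent relations.

        ``relations`` is a subset of ``{"is_a", "part_of"}``.  The result
        never contains the query accession itself.
        """
        rels = set(relations)
        bad = rels - {"is_a", "part_of"}
        if bad:
            raise ValueError(f"unknown relation kinds: {sorted(bad)}")
        self.lookup_term(accession)
        out: set[str] = set()
        frontier = [accession]
        while frontier:
            term = self._terms[frontier.pop()]
            parents: set[str] = set()
            if "is_a" in rels:
                parents |= term.is_a
            if "part_of" in rels:
                parents |= term.part_of
            for p in parents:
                if p not in out and p != accession:
                    out.add(p)
                    frontier.append(p)
        return out

    def value_requirement(self, accession: str) -> ValueContract:
        """The value contract for a term used as an attribute name."""
        term = self.lookup_term(accession)
        if term.attribute_scope is AttributeScope.NOT_AN_ATTRIBUTE:
            raise NotAnAttributeError(
                f"{accession} ({term.name}) never names an attribute"
            )
        return term.value_contract

    def is_cooperative(self, accession: str) -> bool:
        """True for terms under the cooperative-interaction root MI:1149."""
        if accession == "MI:1149":
            return True
        return "MI:1149" in self.ancestors(accession)


# ---------------------------------------------------------------------------
# Embedded vocabulary: the cooperative-interaction block (MI:1149-MI:1175).
# Term names are stored in lower case, as used in attribute names in curated
# files; the published tables render them in Title Case.
# ---------------------------------------------------------------------------

_NV = ValueContract.NO_VALUE
_IA = AttributeScope.INTERACTION_ATTRIBUTE
_FA = AttributeScope.FEATURE_ATTRIBUTE
_NA = AttributeScope.NOT_AN_ATTRIBUTE

# accession, name, is_a, part_of, value_contract, attribute_scope, definition
_COOPERATIVE_TERMS: list[tuple] = [
    ("MI:1149", "cooperative interaction", (), ("MI:0000",), _NV, _NA,
     "A set of molecular binding events that influence each other either "
     "positively or negatively through allostery or pre-assembly. In this "
     "context, covalent post-translational modifications are considered as "
     "binding events."),
    ("MI:1150", "affected interaction", ("MI:0664",), ("MI:1149",),
     ValueContract.INTERACTION_ID, _IA,
     "For an interaction that has a cooperative effect on a subsequent "
     "interaction, this term indicates which subsequent interaction is "
     "affected. The affected interaction is identified by referring to its "
     "interaction id."),
    ("MI:1151", "participant-ref", ("MI:0668",), (),
     ValueContract.PARTICIPANT_ID, _FA,
     "Referring to a previously described interaction as a participant "
     "allows the description of ordered assembly of molecular complexes. "
     "When one of the components of the preformed complex has a feature, "
     "the participant-ref term indicates on which component this feature is "
     "located, by referring to its participant id in the previous "
     "interaction."),
    ("MI:1152", "cooperative effect value", ("MI:0664",), ("MI:1149",),
     ValueContract.FOLD_CHANGE, _IA,
     "This value quantifies the cooperative effect of an interaction on a "
     "subsequent interaction. It is the fold change of the affinity or a "
     "catalytic parameter of a molecule for one ligand in the absence, "
     "versus presence, of a second ligand or a PTM."),
    ("MI:1153", "cooperative effect outcome", (), ("MI:1149",), _NV, _NA,
     "For an interaction that has a cooperative effect on a subsequent "
     "interaction, this term indicates whether this effect is positive or "
     "negative, i.e. whether the subsequent interaction is augmented or "
     "diminished."),
    ("MI:1154", "positive cooperative effect", ("MI:0664", "MI:1153"), (),
     _NV, _IA,
     "This term specifies that an interaction augments a subsequent "
     "interaction."),
    ("MI:1155", "negative cooperative effect", ("MI:0664", "MI:1153"), (),
     _NV, _IA,
     "This term specifies that an interaction diminishes a subsequent "
     "interaction."),
    ("MI:1156", "cooperative mechanism", (), ("MI:1149",), _NV, _NA,
     "For an interaction that has a cooperative effect on a subsequent "
     "interaction, this term indicates the process that mediates this "
     "effect."),
    ("MI:1157", "allostery", ("MI:0664", "MI:1156"), (), _NV, _IA,
     "Reciprocal energetic coupling between two binding events at distinct "
     "sites on the same molecule. The first binding event alters the "
     "binding or catalytic properties of the molecule for the second "
     "binding event."),
    ("MI:1158", "pre-assembly", ("MI:0664", "MI:1156"), (), _NV, _IA,
     "A non-allosteric mechanism where the strength of an interaction "
     "depends on whether or not a particular molecular complex already "
     "exists."),
    ("MI:1159", "allosteric molecule", ("MI:0500", "MI:0664"), ("MI:1149",),
     ValueContract.PARTICIPANT_ID, _IA,
     "A molecule whose binding or catalytic properties at one site are "
     "altered by allosteric PTM or binding of an allosteric effector at a "
     "distinct site. An allosteric molecule is identified by referring to "
     "its participant id."),
    ("MI:1160", "allosteric effector", ("MI:0500", "MI:0664"), ("MI:1149",),
     ValueContract.PARTICIPANT_ID, _IA,
     "A ligand that elicits an allosteric response on binding to a target "
     "molecule."),
    ("MI:1161", "allosteric response", (), ("MI:1149",), _NV, _NA,
     "This term describes the effect of an allosteric binding event. It "
     "specifies whether the interaction alters binding or catalytic "
     "properties of the allosteric molecule at a site distinct from the "
     "allosteric site."),
    ("MI:1162", "allosteric k-type response", ("MI:0664", "MI:1161"), (),
     _NV, _IA,
     "An allosteric response in which the affinity of a molecule is "
     "altered."),
    ("MI:1163", "allosteric v-type response", ("MI:0664", "MI:1161"), (),
     _NV, _IA,
     "An allosteric response in which catalysis (kcat or Vmax) of an enzyme "
     "is altered."),
    ("MI:1164", "allosteric mechanism", (), ("MI:1149",), _NV, _NA,
     "The process that mediates the allosteric response of a molecule on "
     "allosteric PTM or binding of an allosteric effector."),
    ("MI:1165", "allosteric change in structure", ("MI:0664", "MI:1164"), (),
     _NV, _IA,
     "The allosteric mechanism where changes in the local structure of an "
     "allosteric molecule result in altered binding or catalytic "
     "properties."),
    ("MI:1166", "allosteric change in dynamics", ("MI:0664", "MI:1164"), (),
     _NV, _IA,
     "The allosteric mechanism where changes in the local dynamics of an "
     "allosteric molecule result in altered binding or catalytic "
     "properties."),
    ("MI:1167", "allostery type", (), ("MI:1149",), _NV, _NA,
     "This term indicates the chemical relationship between the two ligands "
     "whose binding is allosterically coupled."),
    ("MI:1168", "heterotropic allostery", ("MI:0664", "MI:1167"), (),
     _NV, _IA,
     "The type of allostery that occurs when the two ligands whose binding "
     "is allosterically coupled are not chemically identical."),
    ("MI:1169", "homotropic allostery", ("MI:0664", "MI:1167"), (),
     _NV, _IA,
     "The type of allostery that occurs when the two ligands whose binding "
     "is allosterically coupled are chemically identical."),
    ("MI:1170", "pre-assembly response", (), ("MI:1149",), _NV, _NA,
     "This term describes the way in which preformation of a molecular "
     "complex has a non-allosteric cooperative effect on subsequent "
     "interactions of its components."),
    ("MI:1171", "composite binding site formation", ("MI:0664", "MI:1170"),
     (), _NV, _IA,
     "The preformation of a complex results in the generation of a "
     "continuous binding site that spans more than one component of this "
     "complex. The functional binding site does not exist outside the "
     "context of the preformed complex."),
    ("MI:1172", "altered physicochemical compatibility",
     ("MI:0664", "MI:1170"), (), _NV, _IA,
     "The addition of a PTM to an interaction interface affects the "
     "physicochemical compatibility of the binding site with its binding "
     "partner. This can either induce or enhance an interaction, or result "
     "in inhibition or even abrogation of an interaction."),
    ("MI:1173", "binding site hiding", ("MI:0664", "MI:1170"), (), _NV, _IA,
     "The occurrence of overlapping or adjacent, mutually exclusive binding "
     "sites promotes competitive binding. Binding at one site can result in "
     "hiding of the second site, precluding it from interacting while the "
     "hiding molecule is present."),
    ("MI:1174", "configurational pre-organization", ("MI:0664", "MI:1170"),
     (), _NV, _IA,
     "Multivalent ligands form multiple discrete interactions with one or "
     "more binding partners. An initial binding event can pre-organize "
     "other sites for binding, reducing the entropic costs of their "
     "interactions, while the combined strength of multiple interactions "
     "increases the enthalpic stability of each (avidity effect)."),
    ("MI:1175", "allosteric ptm", ("MI:0252", "MI:0664"), ("MI:1149",),
     ValueContract.FEATURE_ID, _IA,
     "A post-translational modification that elicits an allosteric response "
     "on addition to a target molecule. An allosteric PTM is identified by "
     "referring to its feature id."),
]


def builtin_registry() -> CvRegistry:
    """The embedded cooperative-interaction vocabulary plus external stubs."""
    terms = [
        CvTerm(accession=acc, name=name) for acc, name in EXTERNAL_STUBS.items()
    ]
    for acc, name, is_a, part_of, contract, scope, definition in _COOPERATIVE_TERMS:
        terms.append(
            CvTerm(
                accession=acc,
                name=name,
                definition=definition,
                is_a=frozenset(is_a),
                part_of=frozenset(part_of),
                value_contract=contract,
                attribute_scope=scope,
            )
        )
    return CvRegistry(terms)


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file serialization
# ---------------------------------------------------------------------------

_OBO_HEADER = "format-version: 1.2\nontology: mi-cooperative\n"


def _obo_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _obo_unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def export_obo(registry: CvRegistry) -> str:
    """Serialize a registry as OBO 1.2 ``[Term]`` stanzas.

    Value contracts and attribute scopes ride along as ``property_value``
    lines so the export is re-importable with identity.
    """
    chunks = [_OBO_HEADER]
    for term in registry:
        lines = ["[Term]", f"id: {term.accession}", f"name: {term.name}"]
        if term.definition:
            lines.append(f'def: "{_obo_escape(term.definition)}" []')
        for parent in sorted(term.is_a):
            lines.append(f"is_a: {parent} ! {registry.lookup_term(parent).name}")
        for parent in sorted(term.part_of):
            lines.append(
                f"relationship: part_of {parent} ! "
                f"{registry.lookup_term(parent).name}"
            )
        if term.value_contract is not ValueContract.NO_VALUE:
            lines.append(
                f"property_value: value_contract {term.value_contract.name}"
            )
        if term.attribute_scope is not AttributeScope.NOT_AN_ATTRIBUTE:
            lines.append(
                f"property_value: attribute_scope {term.attribute_scope.name}"
            )
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"')


def import_obo(text: str) -> CvRegistry:
    """Parse OBO ``[Term]`` stanzas back into a :class:`CvRegistry`.

    Unknown tag lines and unknown relationship types are tolerated and
    ignored by queries.  Malformed stanzas raise :class:`ParseError` with
    the offending line number.
    """
    terms: list[CvTerm] = []
    seen: set[str] = set()
    current: dict | None = None
    current_start = 0

    def flush():
        nonlocal current
        if current is None:
            return
        if "accession" not in current:
            raise ParseError("[Term] stanza has no id line", current_start)
        if current["accession"] in seen:
            raise ParseError(
                f"duplicate accession {current['accession']}", current_start
            )
        if "name" not in current:
            raise ParseError(
                f"term {current['accession']} has no name line", current_start
            )
        seen.add(current["accession"])
        try:
            terms.append(
                CvTerm(
                    accession=current["accession"],
                    name=current["name"],
                    definition=current.get("definition", ""),
                    is_a=frozenset(current["is_a"]),
                    part_of=frozenset(current["part_of"]),
                    value_contract=current.get("value_contract", _NV),
                    attribute_scope=current.get("attribute_scope", _NA),
                )
            )
        except InvariantError as exc:
            raise ParseError(str(exc), current_start) from exc
        current = None

    in_term = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                current = {"is_a": [], "part_of": []}
                current_start = lineno
            continue
        if not in_term:
            continue  # header or foreign stanza content
        if ":" not in line:
            raise ParseError(f"not a tag-value line: {line!r}", lineno)
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            if not value:
                raise ParseError("empty id", lineno)
            current["accession"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "def":
            m = _DEF_RE.match(value)
            if not m:
                raise ParseError(f"unquoted def: {value!r}", lineno)
            current["definition"] = _obo_unescape(m.group(1))
        elif tag == "is_a":
            current["is_a"].append(value.split("!")[0].strip())
        elif tag == "relationship":
            parts = value.split("!")[0].split()
            if len(parts) != 2:
                raise ParseError(f"malformed relationship: {value!r}", lineno)
            rel, target = parts
            if rel == "part_of":
                current["part_of"].append(target)
            # other relationship types preserved in OBO but ignored here
        elif tag == "property_value":
            parts = value.split()
            if len(parts) == 2 and parts[0] == "value_contract":
                try:
                    current["value_contract"] = ValueContract[parts[1]]
                except KeyError:
                    raise ParseError(f"unknown contract {parts[1]!r}", lineno)
            elif len(parts) == 2 and parts[0] == "attribute_scope":
                try:
                    current["attribute_scope"] = AttributeScope[parts[1]]
                except KeyError:
                    raise ParseError(f"unknown scope {parts[1]!r}", lineno)
        # unknown tags ignored
    flush()
    try:
        return CvRegistry(terms)
    except InvariantError as exc:
        raise ParseError(str(exc)) from exc
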