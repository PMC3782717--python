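"""In-memory data model for the PSI-MI XML 2.5 entry subset.

The modeled subset is the compact (id-referenced) form of the six entry
child element kinds: source, availabilityList, experimentList,
interactorList, interactionList and attributeList.  A participant of an
interaction references either a single interactor or a *previously
described interaction* — the latter is how ordered complex assembly is
expressed: the participant stands for the pre-formed complex produced by
the referenced binding event.

Ids are bare positive integers, unique per element class within an entry
(experiments, interactors, interactions, participants and features each
form their own id space).  Cross-class collisions are legal; curated files
use them freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .cv import MI_PATTERN
from .errors import InvariantError, UnknownIdError

__all__ = [
    "Attribute",
    "Xref",
    "CvRef",
    "ExperimentDescription",
    "Interactor",
    "Feature",
    "Participant",
    "Interaction",
    "Entry",
    "EntrySet",
    "ReferenceReport",
    "resolve_references",
    "find_participant",
    "find_feature",
]


@dataclass
class Attribute:
    """A semi-structured annotation: a required name, an optional CV
    accession controlling the name, and an optional string value."""

    name: str
    name_ac: Optional[str] = None
    value: Optional[str] = None

    def __post_init__(self):
        if not self.name:
            raise InvariantError("attribute name must be non-empty")
        if self.name_ac is not None and not MI_PATTERN.match(self.name_ac):
            raise InvariantError(
                f"attribute nameAc {self.name_ac!r} does not match MI:NNNN"
            )


@dataclass
class Xref:
    """A cross-reference into an external resource (e.g. DIP, UniProt)."""

    db: str
    id: str
    ref_type: Optional[str] = None

    def __post_init__(self):
        if not self.db or not self.id:
            raise InvariantError("xref db and id must be non-empty")


@dataclass
class CvRef:
    """A (accession, name) pair pointing at a PSI-MI CV term, used for
    interaction types, detection methods, feature types and roles."""

    accession: str
    name: str

    def __post_init__(self):
        if not MI_PATTERN.match(self.accession):
            raise InvariantError(
                f"CV reference {self.accession!r} does not match MI:NNNN"
            )


def _check_id(id: int, what: str) -> None:
    if not isinstance(id, int) or isinstance(id, bool) or id <= 0:
        raise InvariantError(f"{what} id must be a positive integer, got {id!r}")


@dataclass
class ExperimentDescription:
    id: int
    bibref: Xref
    interaction_detection_method: CvRef
    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self):
        _check_id(self.id, "experiment")


@dataclass
class Interactor:
    id: int
    short_label: str
    interactor_type: CvRef
    full_name: Optional[str] = None
    organism_taxid: Optional[int] = None
    xref: Optional[Xref] = None

    def __post_init__(self):
        _check_id(self.id, "interactor")
        if not self.short_label:
            raise InvariantError(f"interactor {self.id} has empty short label")


#: Sentinel range for features whose sequence position is undetermined.
UNDETERMINED = None


@dataclass
class Feature:
    """A sequence feature of a participant, e.g. a phosphorylated residue.

    ``ranges`` holds 1-based inclusive (begin, end) pairs; ``None`` marks an
    undetermined range.
    """

    id: int
    feature_type: CvRef
    ranges: list[Optional[tuple[int, int]]] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self):
        _check_id(self.id, "feature")
        for rng in self.ranges:
            if rng is None:
                continue
            begin, end = rng
            if not (1 <= begin <= end):
                raise InvariantError(
                    f"feature {self.id}: range {rng!r} violates 1 <= begin <= end"
                )


@dataclass
class Participant:
    """One molecule's role in an interaction.

    Exactly one of ``interactor_ref`` (a plain molecule) or
    ``interaction_ref`` (a pre-formed complex, i.e. the product of a prior
    interaction) must be set.
    """

    id: int
    interactor_ref: Optional[int] = None
    interaction_ref: Optional[int] = None
    biological_role: Optional[CvRef] = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        _check_id(self.id, "participant")
        if (self.interactor_ref is None) == (self.interaction_ref is None):
            raise InvariantError(
                f"participant {self.id}: exactly one of interactorRef/"
                "interactionRef must be set"
            )


@dataclass
class Interaction:
    id: int
    short_label: str
    participants: list[Participant]
    xref: Optional[Xref] = None
    experiment_refs: list[int] = field(default_factory=list)
    interaction_type: Optional[CvRef] = None
    attributes: list[Attribute] = field(default_factory=list)

    def __post_init__(self):
        _check_id(self.id, "interaction")
        if not self.participants:
            raise InvariantError(
                f"interaction {self.id} must have at least one participant"
            )


def _check_unique(ids: list[int], what: str) -> None:
    seen: set[int] = set()
    for i in ids:
        if i in seen:
            raise InvariantError(f"duplicate {what} id {i}")
        seen.add(i)


@dataclass
class Entry:
    """One self-contained unit of interaction data."""

    source: Optional[str] = None
    experiments: list[ExperimentDescription] = field(default_factory=list)
    interactors: list[Interactor] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    attributes: list[Attribute] = field(default_factory=list)
    #: Verbatim XML text of entry-level elements outside the modeled subset
    #: (e.g. availabilityList content), keyed by local tag name; re-emitted
    #: on write so unmodeled data round-trips.
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        _check_unique([e.id for e in self.experiments], "experiment")
        _check_unique([i.id for i in self.interactors], "interactor")
        _check_unique([i.id for i in self.interactions], "interaction")
        _check_unique(
            [p.id for i in self.interactions for p in i.participants],
            "participant",
        )
        _check_unique(
            [
                f.id
                for i in self.interactions
                for p in i.participants
                for f in p.features
            ],
            "feature",
        )

    # -- indexed access ---------------------------------------------------

    def experiment(self, id: int) -> ExperimentDescription:
        for e in self.experiments:
            if e.id == id:
                return e
        raise UnknownIdError(f"no experiment with id {id}")

    def interactor(self, id: int) -> Interactor:
        for i in self.interactors:
            if i.id == id:
                return i
        raise UnknownIdError(f"no interactor with id {id}")

    def interaction(self, id: int) -> Interaction:
        for i in self.interactions:
            if i.id == id:
                return i
        raise UnknownIdError(f"no interaction with id {id}")

    def iter_participants(self) -> Iterator[tuple[Interaction, Participant]]:
        for inter in self.interactions:
            for p in inter.participants:
                yield inter, p


@dataclass
class EntrySet:
    """The entrySet root: format level/version markers plus entries."""

    entries: list[Entry]
    level: int = 2
    version: int = 5
    minor_version: int = 4

    def __post_init__(self):
        if not self.entries:
            raise InvariantError("an entrySet must contain at least one entry")
        if (self.level, self.version, self.minor_version) != (2, 5, 4):
            raise InvariantError(
                "entrySet must declare PSI-MI level 2, version 5, minor 4; "
                f"got {(self.level, self.version, self.minor_version)}"
            )


@dataclass
class ReferenceReport:
    """All unresolved references in an entry.  Empty iff the entry is
    referentially closed."""

    dangling: list[tuple[str, str, int]] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy when there ARE problems
        return bool(self.dangling)

    @property
    def ok(self) -> bool:
        return not self.dangling


def resolve_references(entry: Entry) -> ReferenceReport:
    """Check every experimentRef, interactorRef and interactionRef.

    Participant interactionRefs must point at *another* interaction in the
    entry: a participant referencing its own enclosing interaction (directly
    or through a reference cycle) breaks the partial order that sequential
    assembly requires, and is reported as dangling with kind
    ``interactionRef(cycle)``.
    """
    report = ReferenceReport()
    experiment_ids = {e.id for e in entry.experiments}
    interactor_ids = {i.id for i in entry.interactors}
    interaction_ids = {i.id for i in entry.interactions}

    # direct resolution
    for inter in entry.interactions:
        base = f"interaction[{inter.id}]"
        for ref in inter.experiment_refs:
            if ref not in experiment_ids:
                report.dangling.append((base, "experimentRef", ref))
        for p in inter.participants:
            path = f"{base}/participant[{p.id}]"
            if p.interactor_ref is not None and p.interactor_ref not in interactor_ids:
                report.dangling.append((path, "interactorRef", p.interactor_ref))
            if p.interaction_ref is not None:
                if p.interaction_ref not in interaction_ids:
                    report.dangling.append(
                        (path, "interactionRef", p.interaction_ref)
                    )
                elif p.interaction_ref == inter.id:
                    report.dangling.append(
                        (path, "interactionRef(cycle)", p.interaction_ref)
                    )

    # transitive participant-as-interaction cycles (A consumes B, B consumes A)
    consumes: dict[int, set[int]] = {
        i.id: {
            p.interaction_ref
            for p in i.participants
            if p.interaction_ref is not None
            and p.interaction_ref in interaction_ids
            and p.interaction_ref != i.id
        }
        for i in entry.interactions
    }
    # iterative DFS cycle detection over the consumes relation
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {i: WHITE for i in consumes}
    for start in sorted(consumes):
        if colour[start] != WHITE:
            continue
        stack: list[tuple[int, Iterator[int]]] = [
            (start, iter(sorted(consumes[start])))
        ]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == GREY:
                    report.dangling.append(
                        (f"interaction[{node}]", "interactionRef(cycle)", nxt)
                    )
                elif colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(sorted(consumes[nxt]))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()
    return report


def find_participant(
    entry: Entry, interaction_id: int, participant_id: int
) -> Participant:
    """The participant with ``participant_id`` inside one interaction."""
    inter = entry.interaction(interaction_id)  # raises UnknownIdError
    for p in inter.participants:
        if p.id == participant_id:
            return p
    raise UnknownIdError(
        f"interaction {interaction_id} has no participant {participant_id}"
    )


def find_feature(
    entry: Entry, feature_id: int
) -> tuple[Interaction, Participant, Feature]:
    """Locate a feature anywhere in the entry; returns its containment
    chain (interaction, participant, feature)."""
    for inter, p in entry.iter_participants():
        for f in p.features:
            if f.id == feature_id:
                return inter, p, f
    raise UnknownIdError(f"no feature with id {feature_id}")
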