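"""Cooperative-effect extraction and semantic validation.

A cooperative effect is curated inside the ``attributeList`` of the
interaction that *exerts* the effect, as a bundle of CV-named attributes:
the mechanism (allostery or pre-assembly), the affected interaction (by
interaction id), the outcome (positive/negative), an optional fold-change
value, and mechanism-specific slots — for allostery the allosterically
regulated participant, the effector participant or eliciting PTM feature,
the response kind (k-type alters affinity, v-type alters catalysis), the
mediating mechanism (structure vs dynamics) and the allostery type
(homo/heterotropic); for pre-assembly the response class (composite binding
site formation, altered physicochemical compatibility, binding site hiding,
configurational pre-organization).

Only one cooperative effect may be described per interaction record; a
binding event with several effects is curated as repeated records.  The
:func:`validate` rule catalogue (codes COOP01-COOP11) checks exactly these
conventions and reports findings rather than raising.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Optional

from .cv import AttributeScope, CvRegistry, ValueContract
from .errors import (
    AmbiguityError,
    EffectExtractionError,
    InvariantError,
    UnknownTermError,
    ValueFormatError,
)
from .model import Attribute, Entry, Interaction

__all__ = [
    "Mechanism",
    "Outcome",
    "AllostericResponse",
    "AllostericMechanismKind",
    "AllosteryType",
    "PreassemblyResponse",
    "CooperativeEffect",
    "Severity",
    "ValidationFinding",
    "extract_effects",
    "validate",
    "effect_value_parse",
    "findings_to_jsonl",
    "RULE_CODES",
]


class Mechanism(enum.Enum):
    ALLOSTERY = "MI:1157"
    PRE_ASSEMBLY = "MI:1158"


class Outcome(enum.Enum):
    POSITIVE = "MI:1154"
    NEGATIVE = "MI:1155"
    UNSPECIFIED = None


class AllostericResponse(enum.Enum):
    K_TYPE = "MI:1162"
    V_TYPE = "MI:1163"


class AllostericMechanismKind(enum.Enum):
    STRUCTURE = "MI:1165"
    DYNAMICS = "MI:1166"


class AllosteryType(enum.Enum):
    HETEROTROPIC = "MI:1168"
    HOMOTROPIC = "MI:1169"


class PreassemblyResponse(enum.Enum):
    COMPOSITE_BINDING_SITE = "MI:1171"
    ALTERED_PHYSICOCHEMICAL = "MI:1172"
    BINDING_SITE_HIDING = "MI:1173"
    CONFIGURATIONAL_PREORGANIZATION = "MI:1174"


# attribute-name accessions used by the conventions
_AFFECTED = "MI:1150"
_PARTICIPANT_REF = "MI:1151"
_EFFECT_VALUE = "MI:1152"
_MOLECULE = "MI:1159"
_EFFECTOR = "MI:1160"
_PTM = "MI:1175"
_INFERRED_METHODS = {"MI:0363", "MI:0364"}

_MECHANISM_ACS = {m.value for m in Mechanism}
_OUTCOME_ACS = {o.value for o in Outcome if o.value}
_RESPONSE_ACS = {r.value for r in AllostericResponse}
_ALLO_MECH_ACS = {m.value for m in AllostericMechanismKind}
_ALLO_TYPE_ACS = {t.value for t in AllosteryType}
_PREASSEMBLY_ACS = {p.value for p in PreassemblyResponse}
_ALLOSTERY_ONLY_ACS = (
    _RESPONSE_ACS | _ALLO_MECH_ACS | _ALLO_TYPE_ACS
    | {_MOLECULE, _EFFECTOR, _PTM}
)

RULE_CODES = tuple(f"COOP{i:02d}" for i in range(1, 12))


@dataclass
class CooperativeEffect:
    """One resolved cooperative-effect record."""

    source_interaction_id: int
    mechanism: Mechanism
    affected_interaction_id: int
    outcome: Outcome = Outcome.UNSPECIFIED
    effect_value: Optional[float] = None
    allosteric_molecule_id: Optional[int] = None
    allosteric_effector_id: Optional[int] = None
    allosteric_ptm_feature_id: Optional[int] = None
    response: Optional[AllostericResponse] = None
    allosteric_mechanism: Optional[AllostericMechanismKind] = None
    allostery_type: Optional[AllosteryType] = None
    preassembly_response: Optional[PreassemblyResponse] = None

    def __post_init__(self):
        where = f"effect of interaction {self.source_interaction_id}"
        if self.effect_value is not None and not self.effect_value > 0:
            raise InvariantError(
                f"{where}: effect value must be a positive fold change"
            )
        if self.mechanism is Mechanism.ALLOSTERY:
            if self.preassembly_response is not None:
                raise InvariantError(
                    f"{where}: allostery excludes a pre-assembly response"
                )
            if self.allosteric_molecule_id is None:
                raise InvariantError(
                    f"{where}: allostery requires an allosteric molecule"
                )
            has_effector = self.allosteric_effector_id is not None
            has_ptm = self.allosteric_ptm_feature_id is not None
            if has_effector == has_ptm:
                raise InvariantError(
                    f"{where}: allostery requires exactly one of allosteric "
                    "effector / allosteric PTM"
                )
        else:  # PRE_ASSEMBLY
            if self.preassembly_response is None:
                raise InvariantError(
                    f"{where}: pre-assembly requires a response class"
                )
            allo = (
                self.allosteric_molecule_id,
                self.allosteric_effector_id,
                self.allosteric_ptm_feature_id,
                self.response,
                self.allosteric_mechanism,
                self.allostery_type,
            )
            if any(slot is not None for slot in allo):
                raise InvariantError(
                    f"{where}: pre-assembly forbids allostery-specific slots"
                )


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class ValidationFinding:
    code: str
    severity: Severity
    path: str
    message: str

    def __post_init__(self):
        if self.code not in RULE_CODES:
            raise InvariantError(f"unknown rule code {self.code!r}")


def findings_to_jsonl(findings: list[ValidationFinding]) -> str:
    """One JSON object per line: code, severity, path, message."""
    return "\n".join(
        json.dumps(
            {
                "code": f.code,
                "severity": f.severity.value,
                "path": f.path,
                "message": f.message,
            }
        )
        for f in findings
    )


def effect_value_parse(text: str) -> float:
    """Parse a cooperative-effect value: a dimensionless positive fold
    change of an affinity or catalytic parameter, in plain decimal or
    scientific notation.  1.0 means no change; direction is carried by the
    positive/negative outcome, not the value."""
    try:
        value = float(text)
    except (TypeError, ValueError):
        raise ValueFormatError(
            f"effect value {text!r} is not a number"
        ) from None
    if not value > 0 or value != value or value == float("inf"):
        raise ValueFormatError(
            f"effect value must be a positive finite fold change, got {text!r}"
        )
    return value


# ---------------------------------------------------------------------------
# attribute resolution
# ---------------------------------------------------------------------------


def _resolve_attribute(
    attr: Attribute, registry: CvRegistry, strict: bool
) -> tuple[Optional[str], bool]:
    """Map an attribute to a CV accession.

    Returns ``(accession or None, name_mismatch)``.  Resolution prefers the
    accession (``nameAc``); the free-text name is the fallback.  A
    ``name_mismatch`` is reported when both are present but disagree.
    """
    mismatch = False
    if attr.name_ac is not None and attr.name_ac in registry:
        term = registry.lookup_term(attr.name_ac)
        if strict:
            mismatch = attr.name != term.name
        else:
            mismatch = attr.name.lower() != term.name.lower()
        return term.accession, mismatch
    try:
        term = registry.term_by_name(attr.name, lenient=not strict)
        return term.accession, False
    except (UnknownTermError, AmbiguityError):
        return None, False


def _cooperative_attributes(
    interaction: Interaction, registry: CvRegistry, strict: bool = False
) -> list[tuple[Attribute, str, bool]]:
    """The interaction's attributes that resolve to cooperative CV terms
    (anything under the cooperative-interaction root), with mismatch flags."""
    out = []
    for attr in interaction.attributes:
        accession, mismatch = _resolve_attribute(attr, registry, strict)
        if accession is not None and registry.is_cooperative(accession):
            out.append((attr, accession, mismatch))
    return out


def _value_int(attr: Attribute) -> Optional[int]:
    if attr.value is None:
        return None
    try:
        return int(attr.value.strip())
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_effects(
    entry: Entry, registry: CvRegistry, strict: bool = False
) -> list[CooperativeEffect]:
    """One :class:`CooperativeEffect` per interaction record whose attribute
    list names at least one cooperative CV term.

    Attribute names are resolved via ``nameAc`` first, free-text name
    second; non-cooperative attributes are ignored.  Records that cannot be
    assembled into a well-formed effect raise
    :class:`EffectExtractionError`; run :func:`validate` first to obtain
    findings instead of an exception.  In ``strict`` mode a nameAc/name
    disagreement raises immediately.
    """
    effects = []
    for interaction in entry.interactions:
        resolved = _cooperative_attributes(interaction, registry, strict)
        if not resolved:
            continue
        where = f"interaction[{interaction.id}]"
        if strict:
            for attr, accession, mismatch in resolved:
                if mismatch:
                    raise EffectExtractionError(
                        f"{where}: attribute name {attr.name!r} disagrees "
                        f"with nameAc {accession}"
                    )
        by_ac: dict[str, list[Attribute]] = {}
        for attr, accession, _ in resolved:
            by_ac.setdefault(accession, []).append(attr)

        def single(acs: set[str] | str, what: str) -> Optional[str]:
            acs = {acs} if isinstance(acs, str) else acs
            hits = [ac for ac in sorted(acs) if ac in by_ac]
            total = sum(len(by_ac[ac]) for ac in hits)
            if total > 1:
                raise EffectExtractionError(
                    f"{where}: more than one {what} attribute"
                )
            return hits[0] if hits else None

        mech_ac = single(_MECHANISM_ACS, "mechanism")
        if mech_ac is None:
            raise EffectExtractionError(f"{where}: no mechanism attribute")
        affected_ac = single(_AFFECTED, "affected-interaction")
        if affected_ac is None:
            raise EffectExtractionError(
                f"{where}: no affected-interaction attribute"
            )
        affected_id = _value_int(by_ac[_AFFECTED][0])
        if affected_id is None:
            raise EffectExtractionError(
                f"{where}: affected-interaction value is not an integer"
            )
        outcome_ac = single(_OUTCOME_ACS, "outcome")
        value_ac = single(_EFFECT_VALUE, "effect-value")
        effect_value = (
            effect_value_parse(by_ac[_EFFECT_VALUE][0].value or "")
            if value_ac
            else None
        )

        def slot_int(ac: str, what: str) -> Optional[int]:
            if single(ac, what) is None:
                return None
            v = _value_int(by_ac[ac][0])
            if v is None:
                raise EffectExtractionError(
                    f"{where}: {what} value is not an integer id"
                )
            return v

        try:
            effects.append(
                CooperativeEffect(
                    source_interaction_id=interaction.id,
                    mechanism=Mechanism(mech_ac),
                    affected_interaction_id=affected_id,
                    outcome=(
                        Outcome(outcome_ac) if outcome_ac else Outcome.UNSPECIFIED
                    ),
                    effect_value=effect_value,
                    allosteric_molecule_id=slot_int(
                        _MOLECULE, "allosteric-molecule"
                    ),
                    allosteric_effector_id=slot_int(
                        _EFFECTOR, "allosteric-effector"
                    ),
                    allosteric_ptm_feature_id=slot_int(_PTM, "allosteric-PTM"),
                    response=(
                        AllostericResponse(single(_RESPONSE_ACS, "response"))
                        if single(_RESPONSE_ACS, "response")
                        else None
                    ),
                    allosteric_mechanism=(
                        AllostericMechanismKind(
                            single(_ALLO_MECH_ACS, "allosteric-mechanism")
                        )
                        if single(_ALLO_MECH_ACS, "allosteric-mechanism")
                        else None
                    ),
                    allostery_type=(
                        AllosteryType(single(_ALLO_TYPE_ACS, "allostery-type"))
                        if single(_ALLO_TYPE_ACS, "allostery-type")
                        else None
                    ),
                    preassembly_response=(
                        PreassemblyResponse(
                            single(_PREASSEMBLY_ACS, "pre-assembly-response")
                        )
                        if single(_PREASSEMBLY_ACS, "pre-assembly-response")
                        else None
                    ),
                )
            )
        except (InvariantError, ValueFormatError) as exc:
            raise EffectExtractionError(str(exc)) from exc
    return effects


# ---------------------------------------------------------------------------
# validation rule catalogue
# ---------------------------------------------------------------------------


def validate(
    entry: Entry, registry: CvRegistry, strict_names: bool = False
) -> list[ValidationFinding]:
    """Apply the cooperative-annotation rule catalogue.

    Rules (stable codes):

    * COOP01 — exactly one mechanism attribute (allostery xor pre-assembly)
      per effect-bearing record.
    * COOP02 — exactly one affected-interaction attribute whose value is an
      integer id of a *different* interaction in the entry.
    * COOP03 — at most one outcome attribute; absence is a warning.
    * COOP04 — the effect value, if present, parses as a positive real.
    * COOP05 — attributes whose term takes no value must be empty (warning).
    * COOP06 — allostery requires a resolvable allosteric molecule that is a
      participant of the source record, plus exactly one of effector/PTM;
      resolution outside the source record downgrades to a warning.
    * COOP07 — pre-assembly requires exactly one response class and forbids
      allostery-specific attributes.
    * COOP08 — at most one each of response / allosteric mechanism /
      allostery type.
    * COOP09 — a participant-ref feature attribute requires the enclosing
      participant to reference an interaction, and its value must be a
      participant id inside that interaction.
    * COOP10 — experiments backing effect records should use an inferred
      detection method (inferred by author/curator) (warning).
    * COOP11 — nameAc present but inconsistent with the term name.

    Returns findings; never raises.  Zero ERROR findings means the entry is
    cooperativity-valid and :func:`extract_effects` will succeed.
    """
    findings: list[ValidationFinding] = []

    def err(code, path, message):
        findings.append(ValidationFinding(code, Severity.ERROR, path, message))

    def warn(code, path, message):
        findings.append(ValidationFinding(code, Severity.WARNING, path, message))

    experiment_by_id = {e.id for e in entry.experiments}
    interaction_ids = {i.id for i in entry.interactions}

    # -- feature-level rules (COOP09, COOP05/COOP11 for feature attributes) --
    for interaction in entry.interactions:
        for participant in interaction.participants:
            ppath = (
                f"interaction[{interaction.id}]/participant[{participant.id}]"
            )
            for feat in participant.features:
                for attr in feat.attributes:
                    accession, mismatch = _resolve_attribute(
                        attr, registry, strict_names
                    )
                    fpath = f"{ppath}/feature[{feat.id}]/attribute[{attr.name}]"
                    if mismatch:
                        err(
                            "COOP11", fpath,
                            f"name {attr.name!r} disagrees with nameAc "
                            f"{attr.name_ac}",
                        )
                    if accession != _PARTICIPANT_REF:
                        continue
                    if participant.interaction_ref is None:
                        err(
                            "COOP09", fpath,
                            "participant-ref on a participant that does not "
                            "reference an interaction",
                        )
                        continue
                    target_pid = _value_int(attr)
                    if target_pid is None:
                        err(
                            "COOP09", fpath,
                            f"participant-ref value {attr.value!r} is not an "
                            "integer participant id",
                        )
                        continue
                    if participant.interaction_ref not in interaction_ids:
                        err(
                            "COOP09", fpath,
                            f"referenced interaction "
                            f"{participant.interaction_ref} not in entry",
                        )
                        continue
                    referenced = entry.interaction(participant.interaction_ref)
                    if target_pid not in {p.id for p in referenced.participants}:
                        err(
                            "COOP09", fpath,
                            f"participant-ref {target_pid} is not a "
                            f"participant of interaction {referenced.id}",
                        )

    # -- interaction-level rules ------------------------------------------
    for interaction in entry.interactions:
        path = f"interaction[{interaction.id}]"
        resolved = _cooperative_attributes(interaction, registry, strict_names)

        # COOP11 applies to every interaction attribute, cooperative or not
        for attr in interaction.attributes:
            accession, mismatch = _resolve_attribute(
                attr, registry, strict_names
            )
            if mismatch:
                err(
                    "COOP11", f"{path}/attribute[{attr.name}]",
                    f"name {attr.name!r} disagrees with nameAc {attr.name_ac}",
                )

        if not resolved:
            continue  # not an effect-bearing record

        by_ac: dict[str, list[Attribute]] = {}
        for attr, accession, _ in resolved:
            by_ac.setdefault(accession, []).append(attr)

        def count(acs) -> int:
            acs = {acs} if isinstance(acs, str) else acs
            return sum(len(by_ac.get(ac, [])) for ac in acs)

        # COOP05: value-less terms must carry no text
        for attr, accession, _ in resolved:
            term = registry.lookup_term(accession)
            if (
                term.value_contract is ValueContract.NO_VALUE
                and term.attribute_scope is AttributeScope.INTERACTION_ATTRIBUTE
                and attr.value not in (None, "")
            ):
                warn(
                    "COOP05", f"{path}/attribute[{attr.name}]",
                    f"attribute {attr.name!r} takes no value but carries "
                    f"{attr.value!r}",
                )

        # COOP01: exactly one mechanism
        n_mech = count(_MECHANISM_ACS)
        mechanism: Optional[Mechanism] = None
        if n_mech != 1:
            err(
                "COOP01", path,
                f"expected exactly one mechanism attribute (allostery xor "
                f"pre-assembly), found {n_mech}",
            )
        else:
            mech_ac = next(ac for ac in _MECHANISM_ACS if ac in by_ac)
            mechanism = Mechanism(mech_ac)

        # COOP02: exactly one affected interaction, resolvable, not self
        n_affected = count(_AFFECTED)
        if n_affected != 1:
            err(
                "COOP02", path,
                f"expected exactly one affected-interaction attribute, "
                f"found {n_affected}",
            )
        else:
            attr = by_ac[_AFFECTED][0]
            target = _value_int(attr)
            if target is None:
                err(
                    "COOP02", f"{path}/attribute[{attr.name}]",
                    f"affected-interaction value {attr.value!r} is not an "
                    "integer interaction id",
                )
            elif target not in interaction_ids:
                err(
                    "COOP02", f"{path}/attribute[{attr.name}]",
                    f"affected interaction {target} does not exist in the "
                    "entry",
                )
            elif target == interaction.id:
                err(
                    "COOP02", f"{path}/attribute[{attr.name}]",
                    "an interaction cannot affect itself",
                )

        # COOP03: at most one outcome; absence is a warning
        n_outcome = count(_OUTCOME_ACS)
        if n_outcome > 1:
            err(
                "COOP03", path,
                f"expected at most one outcome attribute, found {n_outcome}",
            )
        elif n_outcome == 0:
            warn(
                "COOP03", path,
                "no outcome (positive/negative cooperative effect) annotated",
            )

        # COOP04: effect value parses as positive real
        for attr in by_ac.get(_EFFECT_VALUE, []):
            try:
                effect_value_parse(attr.value or "")
            except ValueFormatError as exc:
                err("COOP04", f"{path}/attribute[{attr.name}]", str(exc))

        # COOP08: at most one of each allosteric qualifier kind
        for acs, label in (
            (_RESPONSE_ACS, "allosteric response"),
            (_ALLO_MECH_ACS, "allosteric mechanism"),
            (_ALLO_TYPE_ACS, "allostery type"),
        ):
            n = count(acs)
            if n > 1:
                err(
                    "COOP08", path,
                    f"expected at most one {label} attribute, found {n}",
                )

        # mechanism-conditional rules are skipped when COOP01 already fired
        if mechanism is Mechanism.ALLOSTERY:
            source_pids = {p.id for p in interaction.participants}
            entry_pids = {
                p.id for i in entry.interactions for p in i.participants
            }
            entry_fids = {
                f.id
                for i in entry.interactions
                for p in i.participants
                for f in p.features
            }
            source_fids = {
                f.id for p in interaction.participants for f in p.features
            }

            def check_ref(ac, what, source_ids, entry_ids):
                n = count(ac)
                if n != 1:
                    return n
                attr = by_ac[ac][0]
                ref = _value_int(attr)
                apath = f"{path}/attribute[{attr.name}]"
                if ref is None:
                    err(
                        "COOP06", apath,
                        f"{what} value {attr.value!r} is not an integer id",
                    )
                elif ref in source_ids:
                    pass
                elif ref in entry_ids:
                    warn(
                        "COOP06", apath,
                        f"{what} {ref} resolves outside the source "
                        "interaction record",
                    )
                else:
                    err("COOP06", apath, f"{what} {ref} does not resolve")
                return n

            n_mol = check_ref(
                _MOLECULE, "allosteric molecule", source_pids, entry_pids
            )
            if n_mol != 1:
                err(
                    "COOP06", path,
                    f"allostery requires exactly one allosteric-molecule "
                    f"attribute, found {n_mol}",
                )
            n_eff = count(_EFFECTOR)
            n_ptm = count(_PTM)
            if n_eff + n_ptm != 1:
                err(
                    "COOP06", path,
                    "allostery requires exactly one of allosteric effector / "
                    f"allosteric PTM, found {n_eff} effector(s) and "
                    f"{n_ptm} PTM(s)",
                )
            else:
                if n_eff:
                    check_ref(
                        _EFFECTOR, "allosteric effector", source_pids,
                        entry_pids,
                    )
                else:
                    check_ref(
                        _PTM, "allosteric PTM", source_fids, entry_fids
                    )
        elif mechanism is Mechanism.PRE_ASSEMBLY:
            n_resp = count(_PREASSEMBLY_ACS)
            if n_resp != 1:
                err(
                    "COOP07", path,
                    f"pre-assembly requires exactly one response attribute, "
                    f"found {n_resp}",
                )
            foreign = sorted(
                ac for ac in _ALLOSTERY_ONLY_ACS if ac in by_ac
            )
            if foreign:
                err(
                    "COOP07", path,
                    "pre-assembly record carries allostery-specific "
                    "attributes: " + ", ".join(foreign),
                )

        # COOP10: evidence should be inferred by author/curator
        for ref in interaction.experiment_refs:
            if ref not in experiment_by_id:
                continue  # dangling refs are the model layer's concern
            method = entry.experiment(ref).interaction_detection_method
            if method.accession not in _INFERRED_METHODS:
                warn(
                    "COOP10", f"{path}/experimentRef[{ref}]",
                    f"effect evidence uses detection method "
                    f"{method.accession} ({method.name}); expected inferred "
                    "by author (MI:0363) or inferred by curator (MI:0364)",
                )

    return findings
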