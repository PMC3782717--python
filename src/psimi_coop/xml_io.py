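"""Reader/writer for the PSI-MI XML 2.5 compact form.

Serialization is canonical: entry children in schema sequence order
(source, availabilityList, experimentList, interactorList, interactionList,
attributeList), empty optional lists omitted, attribute XML-attributes
ordered ``name`` then ``nameAc``, two-space indent, UTF-8, and the format
markers level 2 / version 5 / minorVersion 4 on the root.  Reading a written
document reconstructs the model exactly, which makes round-trip testing
meaningful.

Elements outside the modeled subset (availabilityList content, foreign
entry-level elements) are collected verbatim into the entry's ``extras``
store on read and re-emitted on write.
"""

from __future__ import annotations

import importlib.resources
from typing import IO, Union

from lxml import etree

from .errors import ConfigurationError, FormatError, RefError
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
    resolve_references,
)

__all__ = ["MIF_NS", "read_entry_set", "write_entry_set", "validate_against_schema"]

MIF_NS = "net:sf:psidev:mi"
_SCHEMA_RESOURCE = "mif254_subset_synthetic.xsd"

#: entry children the model understands; everything else is an extra
_MODELED_ENTRY_TAGS = {
    "source",
    "experimentList",
    "interactorList",
    "interactionList",
    "attributeList",
}


def _q(tag: str) -> str:
    return f"{{{MIF_NS}}}{tag}"


def _local(el) -> str:
    return etree.QName(el).localname


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _parse(source: Union[str, bytes, IO]) -> etree._Element:
    try:
        if isinstance(source, str):
            root = etree.fromstring(source.encode("utf-8"))
        elif isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed XML: {exc}") from exc
    return root


_blank_stripper = etree.XMLParser(remove_blank_text=True)


def _canonical_extra(el) -> str:
    """Serialize an unmodeled element with insignificant whitespace removed,
    so extras compare equal across read/write cycles regardless of the
    indentation of the surrounding document."""
    raw = etree.tostring(el, encoding="unicode")
    clean = etree.fromstring(raw.encode("utf-8"), parser=_blank_stripper)
    clean.tail = None
    return etree.tostring(clean, encoding="unicode")


def _int_attr(el, name: str, path: str) -> int:
    raw = el.get(name)
    if raw is None:
        raise FormatError(f"{path}: missing required attribute {name!r}")
    try:
        return int(raw)
    except ValueError:
        raise FormatError(
            f"{path}: attribute {name!r} must be an integer, got {raw!r}"
        ) from None


def _text(el) -> str | None:
    if el is None or el.text is None or el.text.strip() == "":
        return None
    return el.text


def _read_names(parent, path: str) -> tuple[str, str | None]:
    names = parent.find(_q("names"))
    if names is None:
        raise FormatError(f"{path}: missing names element")
    short = _text(names.find(_q("shortLabel")))
    if short is None:
        raise FormatError(f"{path}: missing shortLabel")
    return short, _text(names.find(_q("fullName")))


def _read_xref(el) -> Xref | None:
    if el is None:
        return None
    primary = el.find(_q("primaryRef"))
    if primary is None:
        return None
    return Xref(
        db=primary.get("db", ""),
        id=primary.get("id", ""),
        ref_type=primary.get("refType"),
    )


def _read_cv(el, path: str) -> CvRef:
    short, _ = _read_names(el, path)
    xref = _read_xref(el.find(_q("xref")))
    if xref is None:
        raise FormatError(f"{path}: CV element has no xref/primaryRef")
    return CvRef(accession=xref.id, name=short)


def _read_attributes(el) -> list[Attribute]:
    if el is None:
        return []
    out = []
    for attr in el.findall(_q("attribute")):
        out.append(
            Attribute(
                name=attr.get("name", ""),
                name_ac=attr.get("nameAc"),
                value=_text(attr),
            )
        )
    return out


def _read_feature(el, path: str) -> Feature:
    fid = _int_attr(el, "id", path)
    ftype = _read_cv(el.find(_q("featureType")), f"{path}/featureType")
    ranges: list = []
    range_list = el.find(_q("featureRangeList"))
    if range_list is not None:
        for rng in range_list.findall(_q("featureRange")):
            begin = rng.find(_q("begin"))
            end = rng.find(_q("end"))
            if begin is None or end is None:
                ranges.append(None)  # undetermined
            else:
                ranges.append(
                    (
                        _int_attr(begin, "position", f"{path}/featureRange"),
                        _int_attr(end, "position", f"{path}/featureRange"),
                    )
                )
    return Feature(
        id=fid,
        feature_type=ftype,
        ranges=ranges,
        attributes=_read_attributes(el.find(_q("attributeList"))),
    )


def _read_participant(el, path: str, expanded: list) -> Participant:
    pid = _int_attr(el, "id", path)
    interactor_ref = el.find(_q("interactorRef"))
    interaction_ref = el.find(_q("interactionRef"))
    inline = el.find(_q("interactor"))
    iref = None
    if inline is not None and interactor_ref is None and interaction_ref is None:
        # expanded form: lift the inline interactor definition out and
        # rewrite this participant to the compact referenced form
        lifted = _read_interactor(inline, f"{path}/interactor")
        expanded.append(lifted)
        iref = lifted.id
    role = el.find(_q("biologicalRole"))
    features = []
    flist = el.find(_q("featureList"))
    if flist is not None:
        for i, fel in enumerate(flist.findall(_q("feature"))):
            features.append(_read_feature(fel, f"{path}/feature[{i}]"))
    try:
        return Participant(
            id=pid,
            interactor_ref=(
                iref
                if iref is not None
                else (
                    int(interactor_ref.text)
                    if interactor_ref is not None
                    else None
                )
            ),
            interaction_ref=(
                int(interaction_ref.text) if interaction_ref is not None else None
            ),
            biological_role=(
                _read_cv(role, f"{path}/biologicalRole")
                if role is not None
                else None
            ),
            features=features,
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: bad participant reference: {exc}") from exc


def _read_interactor(el, path: str) -> Interactor:
    iid = _int_attr(el, "id", path)
    short, full = _read_names(el, path)
    itype = _read_cv(el.find(_q("interactorType")), f"{path}/interactorType")
    organism = el.find(_q("organism"))
    return Interactor(
        id=iid,
        short_label=short,
        full_name=full,
        interactor_type=itype,
        organism_taxid=(
            _int_attr(organism, "ncbiTaxId", f"{path}/organism")
            if organism is not None
            else None
        ),
        xref=_read_xref(el.find(_q("xref"))),
    )


def _read_entry(el, index: int) -> Entry:
    path = f"entry[{index}]"
    source_label = None
    source_el = el.find(_q("source"))
    if source_el is not None:
        source_label, _ = _read_names(source_el, f"{path}/source")

    experiments = []
    exp_list = el.find(_q("experimentList"))
    if exp_list is not None:
        for eel in exp_list.findall(_q("experimentDescription")):
            epath = f"{path}/experimentDescription"
            bibref = _read_xref(
                eel.find(_q("bibref")).find(_q("xref"))
                if eel.find(_q("bibref")) is not None
                else None
            )
            if bibref is None:
                raise FormatError(f"{epath}: missing bibref")
            experiments.append(
                ExperimentDescription(
                    id=_int_attr(eel, "id", epath),
                    bibref=bibref,
                    interaction_detection_method=_read_cv(
                        eel.find(_q("interactionDetectionMethod")),
                        f"{epath}/interactionDetectionMethod",
                    ),
                    attributes=_read_attributes(eel.find(_q("attributeList"))),
                )
            )

    interactors = []
    ia_list = el.find(_q("interactorList"))
    if ia_list is not None:
        for iel in ia_list.findall(_q("interactor")):
            interactors.append(_read_interactor(iel, f"{path}/interactor"))

    interactions = []
    expanded: list[Interactor] = []
    in_list = el.find(_q("interactionList"))
    if in_list is not None:
        for iel in in_list.findall(_q("interaction")):
            ipath = f"{path}/interaction"
            iid = _int_attr(iel, "id", ipath)
            ipath = f"{path}/interaction[{iid}]"
            short, _ = _read_names(iel, ipath)
            refs = []
            elist = iel.find(_q("experimentList"))
            if elist is not None:
                for ref in elist.findall(_q("experimentRef")):
                    try:
                        refs.append(int(ref.text))
                    except (TypeError, ValueError):
                        raise FormatError(
                            f"{ipath}: non-integer experimentRef {ref.text!r}"
                        ) from None
            participants = []
            plist = iel.find(_q("participantList"))
            if plist is not None:
                for pel in plist.findall(_q("participant")):
                    participants.append(
                        _read_participant(
                            pel, f"{ipath}/participant", expanded
                        )
                    )
            itype_el = iel.find(_q("interactionType"))
            interactions.append(
                Interaction(
                    id=iid,
                    short_label=short,
                    xref=_read_xref(iel.find(_q("xref"))),
                    experiment_refs=refs,
                    participants=participants,
                    interaction_type=(
                        _read_cv(itype_el, f"{ipath}/interactionType")
                        if itype_el is not None
                        else None
                    ),
                    attributes=_read_attributes(iel.find(_q("attributeList"))),
                )
            )

    # lifted expanded-form interactors join the interactor list (dedup by id)
    known = {i.id for i in interactors}
    for lifted in expanded:
        if lifted.id not in known:
            interactors.append(lifted)
            known.add(lifted.id)

    extras: dict[str, str] = {}
    for child in el:
        if not isinstance(child.tag, str):
            continue  # comments / processing instructions
        tag = _local(child)
        if tag not in _MODELED_ENTRY_TAGS:
            extras[tag] = _canonical_extra(child)

    return Entry(
        source=source_label,
        experiments=experiments,
        interactors=interactors,
        interactions=interactions,
        attributes=_read_attributes(el.find(_q("attributeList"))),
        extras=extras,
    )


def read_entry_set(source: Union[str, bytes, IO]) -> EntrySet:
    """Parse a PSI-MI XML 2.5 document into an :class:`EntrySet`.

    Accepts an XML string, UTF-8 bytes, or a file-like/path source.  The
    root must be ``entrySet`` in the PSI-MI 2.5 namespace.  Expanded-form
    interactor definitions inside participants are lifted into the
    interactor list and rewritten as references.
    """
    root = _parse(source)
    if _local(root) != "entrySet":
        raise FormatError(
            f"root element is {_local(root)!r}, expected 'entrySet'"
        )
    if etree.QName(root).namespace != MIF_NS:
        raise FormatError(
            f"root namespace is {etree.QName(root).namespace!r}, "
            f"expected {MIF_NS!r}"
        )
    level = _int_attr(root, "level", "entrySet")
    version = _int_attr(root, "version", "entrySet")
    minor = _int_attr(root, "minorVersion", "entrySet")
    entries = [
        _read_entry(el, i) for i, el in enumerate(root.findall(_q("entry")))
    ]
    if not entries:
        raise FormatError("entrySet contains no entry elements")
    return EntrySet(
        entries=entries, level=level, version=version, minor_version=minor
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _sub(parent, tag: str, text=None, **attrs):
    el = etree.SubElement(parent, _q(tag))
    for k, v in attrs.items():
        el.set(k, str(v))
    if text is not None:
        el.text = str(text)
    return el


def _write_names(parent, short: str, full: str | None = None):
    names = _sub(parent, "names")
    _sub(names, "shortLabel", short)
    if full is not None:
        _sub(names, "fullName", full)


def _write_xref(parent, xref: Xref):
    el = _sub(parent, "xref")
    attrs = {"db": xref.db, "id": xref.id}
    if xref.ref_type is not None:
        attrs["refType"] = xref.ref_type
    _sub(el, "primaryRef", **attrs)


def _write_cv(parent, tag: str, cv: CvRef):
    el = _sub(parent, tag)
    _write_names(el, cv.name)
    xref = _sub(el, "xref")
    _sub(xref, "primaryRef", db="psi-mi", id=cv.accession)


def _write_attributes(parent, attributes: list[Attribute]):
    if not attributes:
        return
    alist = _sub(parent, "attributeList")
    for attr in attributes:
        attrs = {"name": attr.name}
        if attr.name_ac is not None:
            attrs["nameAc"] = attr.name_ac
        _sub(alist, "attribute", text=attr.value, **attrs)


_CERTAIN = CvRef("MI:0335", "certain")
_UNDETERMINED = CvRef("MI:0339", "undetermined")


def _write_feature(parent, feature: Feature):
    fel = _sub(parent, "feature", id=feature.id)
    _write_cv(fel, "featureType", feature.feature_type)
    if feature.ranges:
        rlist = _sub(fel, "featureRangeList")
        for rng in feature.ranges:
            rel = _sub(rlist, "featureRange")
            if rng is None:
                _write_cv(rel, "startStatus", _UNDETERMINED)
                _write_cv(rel, "endStatus", _UNDETERMINED)
            else:
                begin, end = rng
                _write_cv(rel, "startStatus", _CERTAIN)
                _sub(rel, "begin", position=begin)
                _write_cv(rel, "endStatus", _CERTAIN)
                _sub(rel, "end", position=end)
    _write_attributes(fel, feature.attributes)


def _write_entry(parent, entry: Entry):
    eel = _sub(parent, "entry")
    if entry.source is not None:
        sel = _sub(eel, "source")
        _write_names(sel, entry.source)
    if "availabilityList" in entry.extras:
        eel.append(etree.fromstring(entry.extras["availabilityList"].encode()))
    if entry.experiments:
        elist = _sub(eel, "experimentList")
        for exp in entry.experiments:
            xel = _sub(elist, "experimentDescription", id=exp.id)
            bel = _sub(xel, "bibref")
            _write_xref(bel, exp.bibref)
            _write_cv(
                xel, "interactionDetectionMethod",
                exp.interaction_detection_method,
            )
            _write_attributes(xel, exp.attributes)
    if entry.interactors:
        ilist = _sub(eel, "interactorList")
        for mol in entry.interactors:
            mel = _sub(ilist, "interactor", id=mol.id)
            _write_names(mel, mol.short_label, mol.full_name)
            if mol.xref is not None:
                _write_xref(mel, mol.xref)
            _write_cv(mel, "interactorType", mol.interactor_type)
            if mol.organism_taxid is not None:
                _sub(mel, "organism", ncbiTaxId=mol.organism_taxid)
    nlist = _sub(eel, "interactionList")
    for inter in entry.interactions:
        nel = _sub(nlist, "interaction", id=inter.id)
        _write_names(nel, inter.short_label)
        if inter.xref is not None:
            _write_xref(nel, inter.xref)
        if inter.experiment_refs:
            xlist = _sub(nel, "experimentList")
            for ref in inter.experiment_refs:
                _sub(xlist, "experimentRef", text=ref)
        plist = _sub(nel, "participantList")
        for p in inter.participants:
            pel = _sub(plist, "participant", id=p.id)
            if p.interactor_ref is not None:
                _sub(pel, "interactorRef", text=p.interactor_ref)
            else:
                _sub(pel, "interactionRef", text=p.interaction_ref)
            if p.biological_role is not None:
                _write_cv(pel, "biologicalRole", p.biological_role)
            if p.features:
                flist = _sub(pel, "featureList")
                for feat in p.features:
                    _write_feature(flist, feat)
        if inter.interaction_type is not None:
            _write_cv(nel, "interactionType", inter.interaction_type)
        _write_attributes(nel, inter.attributes)
    _write_attributes(eel, entry.attributes)
    # foreign entry-level elements ride along at the end
    for tag, xml_text in entry.extras.items():
        if tag != "availabilityList":
            eel.append(etree.fromstring(xml_text.encode()))


def write_entry_set(entry_set: EntrySet) -> str:
    """Serialize an :class:`EntrySet` as canonical PSI-MI XML 2.5 text.

    Raises :class:`RefError` when any entry carries dangling references —
    a file that cannot be resolved should never be written.
    """
    for i, entry in enumerate(entry_set.entries):
        report = resolve_references(entry)
        if report:
            raise RefError(
                f"entry {i} has dangling references: "
                + "; ".join(
                    f"{path} {kind}={ref}" for path, kind, ref in report.dangling
                )
            )
    root = etree.Element(
        _q("entrySet"),
        nsmap={None: MIF_NS},
        level=str(entry_set.level),
        version=str(entry_set.version),
        minorVersion=str(entry_set.minor_version),
    )
    for entry in entry_set.entries:
        _write_entry(root, entry)
    etree.indent(root, space="  ")
    return etree.tostring(
        root, encoding="UTF-8", xml_declaration=True
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# schema validation
# ---------------------------------------------------------------------------

_schema_cache: etree.XMLSchema | None = None


def _load_schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        try:
            resource = (
                importlib.resources.files("psimi_coop.data") / _SCHEMA_RESOURCE
            )
            with importlib.resources.as_file(resource) as path:
                _schema_cache = etree.XMLSchema(etree.parse(str(path)))
        except (OSError, etree.LxmlError) as exc:
            raise ConfigurationError(
                f"cannot load bundled XSD {_SCHEMA_RESOURCE}: {exc}"
            ) from exc
    return _schema_cache


def validate_against_schema(source: Union[str, bytes, IO]) -> list[str]:
    """Validate a document against the bundled MIF254 subset schema.

    Returns an empty list for schema-valid documents, otherwise one
    ``"line L: message"`` string per violation.
    """
    schema = _load_schema()
    root = _parse(source)
    if schema.validate(root):
        return []
    return [
        f"line {err.line}: {err.message}" for err in schema.error_log
    ]
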