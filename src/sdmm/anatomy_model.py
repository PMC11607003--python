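"""Basic anatomy (BA): hierarchical structures, natural links, landmarks.

The BA is the unmodified reference model every patient record is a delta
against.  Anatomical structures form one tree per functional organ class
(the parent relation encodes where a structure *originates* on its parent),
while directed *natural links* encode function: blood flow, bile flow,
stool propulsion.  Every tubular structure is parameterized by arc length
``[0, length_mm)`` in millimetres, half-open and 0-based; offset 0 is the
proximal (inflow) end.

Models are serialized in a small XML dialect (root ``<basicAnatomy>``); an
XML Schema ships with the package and unknown elements are rejected.
Validation is collect-all: :func:`validate_anatomy` returns a report listing
every violation rather than raising on the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "RELATIONS",
    "OrganClass",
    "AnatomicalStructure",
    "NaturalLink",
    "Landmark",
    "BasicAnatomy",
    "ValidationIssue",
    "ValidationReport",
    "SdmmError",
    "ParseError",
    "ValidationFailure",
    "UnknownIdError",
    "load_basic_anatomy",
    "write_basic_anatomy",
    "validate_anatomy",
    "functional_successors",
    "lookup_landmark",
]

#: Functional relations a link may carry, in canonical order.
RELATIONS = ("luminal", "arterial", "venous", "portal", "biliary", "pancreatic")


# ---------------------------------------------------------------------------
# Errors

class SdmmError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SdmmError):
    """Malformed XML or a document violating the shipped schema."""


class ValidationFailure(SdmmError):
    """A document parsed but violated model invariants.

    Carries the full :class:`ValidationReport` in :attr:`report`.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(str(i) for i in report.issues[:5])
        more = "" if len(report.issues) <= 5 else f" (+{len(report.issues) - 5} more)"
        super().__init__(f"{len(report.issues)} validation issue(s): {lines}{more}")


class UnknownIdError(SdmmError, KeyError):
    """A structure, landmark or link id did not resolve."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass(frozen=True, slots=True)
class OrganClass:
    """Root of one functional organ system (e.g. ``Intestine``)."""

    name: str


@dataclass(frozen=True, slots=True)
class AnatomicalStructure:
    """One tubular structure, parameterized by arc length in mm.

    ``parent_id`` is ``None`` only for the single root of each organ-class
    tree; ``attachment_offset_mm`` is the position along the parent where
    this structure originates.
    """

    id: str
    name: str
    organ_class: str
    parent_id: str | None = None
    attachment_offset_mm: float = 0.0
    length_mm: float = 1.0
    diameter_mm: float = 0.0


@dataclass(frozen=True, slots=True)
class NaturalLink:
    """Directed functional connection; from -> to is physiological flow."""

    from_id: str
    from_offset_mm: float
    to_id: str
    to_offset_mm: float
    relation: str


@dataclass(frozen=True, slots=True)
class Landmark:
    """Named reference point on a structure (e.g. ``ligament_of_treitz``)."""

    name: str
    structure_id: str
    offset_mm: float


@dataclass(frozen=True, slots=True)
class BasicAnatomy:
    """A validated basic anatomy.

    ``structures`` is id-indexed; ``landmarks`` is name-indexed.  Instances
    compare by content, so load -> write -> load is an identity check.
    """

    organ_classes: tuple[OrganClass, ...]
    structures: Mapping[str, AnatomicalStructure]
    natural_links: tuple[NaturalLink, ...]
    landmarks: Mapping[str, Landmark]

    def children_of(self, structure_id: str) -> list[AnatomicalStructure]:
        return [s for s in self.structures.values() if s.parent_id == structure_id]

    def roots(self) -> list[AnatomicalStructure]:
        return [s for s in self.structures.values() if s.parent_id is None]


# ---------------------------------------------------------------------------
# Validation report

@dataclass(frozen=True, slots=True)
class ValidationIssue:
    rule: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.subject}: {self.message}"


@dataclass(frozen=True, slots=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        return not self.issues


def _finite(x: float) -> bool:
    return math.isfinite(x)


def validate_anatomy(ba: BasicAnatomy) -> ValidationReport:
    """Check every model invariant; empty report iff the BA is valid.

    Violations are report entries, never exceptions, and are ordered
    deterministically (by rule, then subject id).
    """
    issues: list[ValidationIssue] = []

    def add(rule: str, subject: str, message: str) -> None:
        issues.append(ValidationIssue(rule, subject, message))

    class_names = [c.name for c in ba.organ_classes]
    if len(set(class_names)) != len(class_names):
        dupes = sorted({n for n in class_names if class_names.count(n) > 1})
        for n in dupes:
            add("duplicate-organ-class", n, "organ class name not unique")

    for sid, s in ba.structures.items():
        if sid != s.id:
            add("index-mismatch", sid, f"indexed under {sid!r} but id is {s.id!r}")
        if s.organ_class not in class_names:
            add("unknown-organ-class", sid, f"organ class {s.organ_class!r} not declared")
        if not (_finite(s.length_mm) and s.length_mm > 0):
            add("non-positive-length", sid, f"length_mm = {s.length_mm}")
        if not (_finite(s.diameter_mm) and s.diameter_mm >= 0):
            add("negative-diameter", sid, f"diameter_mm = {s.diameter_mm}")
        if s.parent_id is not None:
            parent = ba.structures.get(s.parent_id)
            if parent is None:
                add("unresolved-parent", sid, f"parent {s.parent_id!r} does not exist")
            else:
                if parent.organ_class != s.organ_class:
                    add("class-mismatch", sid,
                        f"child class {s.organ_class!r} != parent class {parent.organ_class!r}")
                if not (_finite(s.attachment_offset_mm)
                        and 0 <= s.attachment_offset_mm <= parent.length_mm):
                    add("attachment-out-of-range", sid,
                        f"offset {s.attachment_offset_mm} outside [0, {parent.length_mm}]")

    # forest: one root per class, no parent cycles, full reachability
    roots_by_class: dict[str, list[str]] = {c: [] for c in class_names}
    for sid, s in ba.structures.items():
        if s.parent_id is None and s.organ_class in roots_by_class:
            roots_by_class[s.organ_class].append(sid)
    for cname, roots in sorted(roots_by_class.items()):
        if ba.structures and len(roots) != 1:
            present = any(s.organ_class == cname for s in ba.structures.values())
            if present:
                add("root-count", cname, f"{len(roots)} roots (expected exactly 1)")
    for sid in sorted(ba.structures):
        seen = {sid}
        cur = ba.structures[sid].parent_id
        while cur is not None and cur in ba.structures:
            if cur in seen:
                add("parent-cycle", sid, f"cycle through {cur!r}")
                break
            seen.add(cur)
            cur = ba.structures[cur].parent_id

    for i, link in enumerate(ba.natural_links):
        subj = f"link#{i}({link.from_id}->{link.to_id})"
        if link.relation not in RELATIONS:
            add("unknown-relation", subj, f"relation {link.relation!r}")
        for end, sid, off in (("from", link.from_id, link.from_offset_mm),
                              ("to", link.to_id, link.to_offset_mm)):
            s = ba.structures.get(sid)
            if s is None:
                add("unresolved-link-endpoint", subj, f"{end} structure {sid!r} does not exist")
            elif not (_finite(off) and 0 <= off <= s.length_mm):
                add("link-offset-out-of-range", subj,
                    f"{end} offset {off} outside [0, {s.length_mm}]")
        if link.from_id == link.to_id and link.from_offset_mm == link.to_offset_mm:
            add("self-link", subj, "identical endpoints")

    for name in sorted(ba.landmarks):
        lm = ba.landmarks[name]
        s = ba.structures.get(lm.structure_id)
        if s is None:
            add("unresolved-landmark", name, f"structure {lm.structure_id!r} does not exist")
        elif not (_finite(lm.offset_mm) and 0 <= lm.offset_mm <= s.length_mm):
            add("landmark-out-of-range", name,
                f"offset {lm.offset_mm} outside [0, {s.length_mm}]")

    issues.sort(key=lambda i: (i.rule, i.subject, i.message))
    return ValidationReport(tuple(issues))


# ---------------------------------------------------------------------------
# XML I/O

_BA_SCHEMA: etree.XMLSchema | None = None


def _ba_schema() -> etree.XMLSchema:
    global _BA_SCHEMA
    if _BA_SCHEMA is None:
        text = resources.files("sdmm").joinpath("data/basic_anatomy.xsd").read_bytes()
        _BA_SCHEMA = etree.XMLSchema(etree.fromstring(text))
    return _BA_SCHEMA


def _parse_document(document) -> etree._Element:
    """Accept bytes, str, a path, or a file object; return the root element."""
    try:
        if isinstance(document, bytes):
            return etree.fromstring(document)
        if isinstance(document, str):
            if document.lstrip().startswith("<"):
                return etree.fromstring(document.encode("utf-8"))
            return etree.parse(document).getroot()
        if hasattr(document, "read"):
            return etree.parse(document).getroot()
        return etree.parse(str(document)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ParseError(f"cannot parse XML document: {exc}") from exc


def _fmt(x: float) -> str:
    """Shortest round-tripping decimal for an mm value (deterministic)."""
    f = float(x)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def load_basic_anatomy(document) -> BasicAnatomy:
    """Parse and fully validate a BA document.

    Raises :class:`ParseError` on malformed XML or schema violations and
    :class:`ValidationFailure` (carrying the report) on model invariant
    violations.  ``load(write(load(doc)))`` equals ``load(doc)``.
    """
    root = _parse_document(document)
    schema = _ba_schema()
    if not schema.validate(root):
        raise ParseError("schema violation: "
                         + "; ".join(str(e) for e in schema.error_log))

    classes: list[OrganClass] = []
    structures: dict[str, AnatomicalStructure] = {}
    links: list[NaturalLink] = []
    landmarks: dict[str, Landmark] = {}
    dup_issues: list[ValidationIssue] = []

    for el in root:
        tag = etree.QName(el).localname
        if tag == "organClass":
            classes.append(OrganClass(el.get("name")))
        elif tag == "structure":
            s = AnatomicalStructure(
                id=el.get("id"),
                name=el.get("name"),
                organ_class=el.get("class"),
                parent_id=el.get("parent"),
                attachment_offset_mm=float(el.get("attachmentOffsetMm", "0")),
                length_mm=float(el.get("lengthMm")),
                diameter_mm=float(el.get("diameterMm", "0")),
            )
            if s.id in structures:
                dup_issues.append(ValidationIssue("duplicate-id", s.id, "structure id not unique"))
            structures[s.id] = s
        elif tag == "naturalLink":
            from_id = el.get("from")
            to_id = el.get("to")
            # default endpoints: distal end of the source, proximal end of the target
            from_off = el.get("fromOffsetMm")
            if from_off is None:
                src = structures.get(from_id)
                from_off = src.length_mm if src is not None else 0.0
            links.append(NaturalLink(
                from_id=from_id,
                from_offset_mm=float(from_off),
                to_id=to_id,
                to_offset_mm=float(el.get("toOffsetMm", "0")),
                relation=el.get("relation"),
            ))
        elif tag == "landmark":
            lm = Landmark(el.get("name"), el.get("structure"), float(el.get("offsetMm")))
            if lm.name in landmarks:
                dup_issues.append(ValidationIssue("duplicate-landmark", lm.name,
                                                  "landmark name not unique"))
            landmarks[lm.name] = lm

    ba = BasicAnatomy(tuple(classes), structures, tuple(links), landmarks)
    report = validate_anatomy(ba)
    if dup_issues or not report.ok:
        all_issues = sorted(tuple(dup_issues) + report.issues,
                            key=lambda i: (i.rule, i.subject, i.message))
        raise ValidationFailure(ValidationReport(tuple(all_issues)))
    return ba


def write_basic_anatomy(ba: BasicAnatomy) -> bytes:
    """Serialize a BA to canonical UTF-8 XML bytes.

    Output is byte-stable for equal inputs: structures and landmarks are
    written sorted by id/name, links in stored order, floats in shortest
    round-trip form.
    """
    root = etree.Element("basicAnatomy", version="1")
    for c in ba.organ_classes:
        etree.SubElement(root, "organClass", name=c.name)
    for sid in sorted(ba.structures):
        s = ba.structures[sid]
        attrs = {"id": s.id, "name": s.name, "class": s.organ_class}
        if s.parent_id is not None:
            attrs["parent"] = s.parent_id
            attrs["attachmentOffsetMm"] = _fmt(s.attachment_offset_mm)
        attrs["lengthMm"] = _fmt(s.length_mm)
        attrs["diameterMm"] = _fmt(s.diameter_mm)
        etree.SubElement(root, "structure", **attrs)
    for link in ba.natural_links:
        etree.SubElement(root, "naturalLink", **{
            "from": link.from_id,
            "fromOffsetMm": _fmt(link.from_offset_mm),
            "to": link.to_id,
            "toOffsetMm": _fmt(link.to_offset_mm),
            "relation": link.relation,
        })
    for name in sorted(ba.landmarks):
        lm = ba.landmarks[name]
        etree.SubElement(root, "landmark", name=lm.name,
                         structure=lm.structure_id, offsetMm=_fmt(lm.offset_mm))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# Queries on the BA

def functional_successors(
    ba: BasicAnatomy, structure_id: str, relation: str
) -> list[tuple[str, tuple[float, float]]]:
    """All natural links of ``relation`` leaving ``structure_id``.

    Returns ``(target_id, (from_offset_mm, to_offset_mm))`` pairs in stored
    link order (stable).  Flow direction is from -> to.
    """
    if structure_id not in ba.structures:
        raise UnknownIdError(structure_id)
    return [
        (l.to_id, (l.from_offset_mm, l.to_offset_mm))
        for l in ba.natural_links
        if l.from_id == structure_id and l.relation == relation
    ]


def lookup_landmark(ba: BasicAnatomy, name: str) -> Landmark:
    """Exact, case-sensitive landmark lookup."""
    try:
        return ba.landmarks[name]
    except KeyError:
        raise UnknownIdError(name) from None
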