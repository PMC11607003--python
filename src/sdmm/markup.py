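"""Patient records: dated surgeries whose steps carry narrative + markup.

A record is a list of surgery events over a referenced basic anatomy.
Each event holds numbered steps; a step has free narrative text (preserved
verbatim, written as CDATA) and an ordered list of machine-readable
annotations — resections, reconstructions (artificial links / anastomoses)
and biometric overrides.  Only the annotations (the *deltas*) are needed to
reconstruct the patient's anatomical model; :func:`extract_deltas` projects
them out.

Events are kept sorted ascending by date, ties broken by event id; an
out-of-order document is repaired with a logged warning rather than
rejected.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Union

from lxml import etree

from .anatomy_model import (
    RELATIONS,
    BasicAnatomy,
    ParseError,
    ValidationFailure,
    ValidationIssue,
    ValidationReport,
    _fmt,
    _parse_document,
)

__all__ = [
    "ResectionAnnotation",
    "ReconstructionAnnotation",
    "BiometricAnnotation",
    "Annotation",
    "SurgicalStep",
    "SurgeryEvent",
    "PatientRecord",
    "EventDelta",
    "read_patient_record",
    "write_patient_record",
    "validate_record",
    "extract_deltas",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Annotation types

@dataclass(frozen=True, slots=True)
class ResectionAnnotation:
    """Removal of a whole structure or a half-open interval of it."""

    structure_id: str
    scope: str  # "whole" | "interval"
    start_mm: float | None = None
    end_mm: float | None = None

    @property
    def interval(self) -> tuple[float, float] | None:
        if self.scope == "interval":
            return (self.start_mm, self.end_mm)
        return None


@dataclass(frozen=True, slots=True)
class ReconstructionAnnotation:
    """An artificial link (anastomosis) joining two points.

    ``length_mm`` is the intrinsic length of the connection; an anastomosis
    joins two points, so it defaults to 0.
    """

    link_id: str
    from_id: str
    from_offset_mm: float
    to_id: str
    to_offset_mm: float
    kind: str
    relation: str
    length_mm: float = 0.0


@dataclass(frozen=True, slots=True)
class BiometricAnnotation:
    """Measured override of a structure's length or diameter."""

    structure_id: str
    attribute: str  # "length_mm" | "diameter_mm"
    value: float


Annotation = Union[ResectionAnnotation, ReconstructionAnnotation, BiometricAnnotation]


@dataclass(frozen=True, slots=True)
class SurgicalStep:
    ordinal: int
    narrative: str = ""
    annotations: tuple[Annotation, ...] = ()


@dataclass(frozen=True, slots=True)
class SurgeryEvent:
    event_id: str
    date: _dt.date
    title: str
    steps: tuple[SurgicalStep, ...]

    @property
    def annotations(self) -> tuple[Annotation, ...]:
        return tuple(a for step in self.steps for a in step.annotations)


@dataclass(frozen=True, slots=True)
class PatientRecord:
    patient_id: str
    birth_date: _dt.date
    ba_reference: str
    events: tuple[SurgeryEvent, ...] = ()


@dataclass(frozen=True, slots=True)
class EventDelta:
    """The transferable markup of one surgery: annotations minus narrative."""

    event_id: str
    date: _dt.date
    annotations: tuple[Annotation, ...]


def _event_key(e: SurgeryEvent) -> tuple:
    return (e.date, e.event_id)


# ---------------------------------------------------------------------------
# XML I/O

_RECORD_SCHEMA: etree.XMLSchema | None = None


def _record_schema() -> etree.XMLSchema:
    global _RECORD_SCHEMA
    if _RECORD_SCHEMA is None:
        text = resources.files("sdmm").joinpath("data/patient_record.xsd").read_bytes()
        _RECORD_SCHEMA = etree.XMLSchema(etree.fromstring(text))
    return _RECORD_SCHEMA


def _parse_annotation(el: etree._Element) -> Annotation:
    tag = etree.QName(el).localname
    if tag == "resect":
        scope = el.get("scope")
        start = el.get("startMm")
        end = el.get("endMm")
        return ResectionAnnotation(
            structure_id=el.get("structure"),
            scope=scope,
            start_mm=float(start) if start is not None else None,
            end_mm=float(end) if end is not None else None,
        )
    if tag == "reconstruct":
        return ReconstructionAnnotation(
            link_id=el.get("id"),
            from_id=el.get("from"),
            from_offset_mm=float(el.get("fromOffsetMm")),
            to_id=el.get("to"),
            to_offset_mm=float(el.get("toOffsetMm")),
            kind=el.get("kind"),
            relation=el.get("relation"),
            length_mm=float(el.get("lengthMm", "0")),
        )
    if tag == "biometric":
        return BiometricAnnotation(
            structure_id=el.get("structure"),
            attribute=el.get("attribute"),
            value=float(el.get("value")),
        )
    raise ParseError(f"unknown annotation element <{tag}>")  # pragma: no cover


def read_patient_record(document) -> PatientRecord:
    """Parse and validate a patient record document.

    Intrinsic invariants (dates valid, steps consecutively numbered, no
    event before birth) raise :class:`ValidationFailure`; events stored out
    of order are sorted with a logged warning.
    """
    root = _parse_document(document)
    schema = _record_schema()
    if not schema.validate(root):
        raise ParseError("schema violation: "
                         + "; ".join(str(e) for e in schema.error_log))

    patient_el = root.find("patient")
    birth = _dt.date.fromisoformat(patient_el.get("birthDate"))
    events: list[SurgeryEvent] = []
    issues: list[ValidationIssue] = []
    for surg in root.findall("surgery"):
        steps: list[SurgicalStep] = []
        for step_el in surg.findall("step"):
            narrative_el = step_el.find("narrative")
            narrative = narrative_el.text if narrative_el is not None and narrative_el.text else ""
            annots = tuple(
                _parse_annotation(el) for el in step_el
                if etree.QName(el).localname != "narrative"
            )
            steps.append(SurgicalStep(int(step_el.get("n")), narrative, annots))
        date = _dt.date.fromisoformat(surg.get("date"))
        event = SurgeryEvent(surg.get("id"), date, surg.get("title"), tuple(steps))
        if [s.ordinal for s in steps] != list(range(1, len(steps) + 1)):
            issues.append(ValidationIssue(
                "step-ordinals", event.event_id,
                f"ordinals {[s.ordinal for s in steps]} not consecutive from 1"))
        if not steps:
            issues.append(ValidationIssue("empty-event", event.event_id, "no steps"))
        if date < birth:
            issues.append(ValidationIssue(
                "event-before-birth", event.event_id,
                f"event date {date} precedes birth date {birth}"))
        events.append(event)

    if events != sorted(events, key=_event_key):
        logger.warning("record %s: events out of order; repaired by sorting",
                       patient_el.get("id"))
        events.sort(key=_event_key)
    if issues:
        raise ValidationFailure(ValidationReport(tuple(sorted(
            issues, key=lambda i: (i.rule, i.subject, i.message)))))
    return PatientRecord(
        patient_id=patient_el.get("id"),
        birth_date=birth,
        ba_reference=patient_el.get("baRef"),
        events=tuple(events),
    )


def _annotation_element(parent: etree._Element, a: Annotation) -> None:
    if isinstance(a, ResectionAnnotation):
        attrs = {"structure": a.structure_id, "scope": a.scope}
        if a.scope == "interval":
            attrs["startMm"] = _fmt(a.start_mm)
            attrs["endMm"] = _fmt(a.end_mm)
        etree.SubElement(parent, "resect", **attrs)
    elif isinstance(a, ReconstructionAnnotation):
        attrs = {
            "id": a.link_id,
            "from": a.from_id, "fromOffsetMm": _fmt(a.from_offset_mm),
            "to": a.to_id, "toOffsetMm": _fmt(a.to_offset_mm),
            "kind": a.kind, "relation": a.relation,
        }
        if a.length_mm:
            attrs["lengthMm"] = _fmt(a.length_mm)
        etree.SubElement(parent, "reconstruct", **attrs)
    else:
        etree.SubElement(parent, "biometric", structure=a.structure_id,
                         attribute=a.attribute, value=_fmt(a.value))


def write_patient_record(record: PatientRecord) -> bytes:
    """Serialize a record to canonical UTF-8 XML bytes (byte-deterministic).

    Narrative text is legally sensitive and preserved verbatim, wrapped in
    CDATA.  ``read(write(r)) == r`` for every valid record.
    """
    root = etree.Element("patientRecord", version="1")
    etree.SubElement(root, "patient", id=record.patient_id,
                     birthDate=record.birth_date.isoformat(),
                     baRef=record.ba_reference)
    for event in sorted(record.events, key=_event_key):
        surg = etree.SubElement(root, "surgery", id=event.event_id,
                                date=event.date.isoformat(), title=event.title)
        for step in event.steps:
            step_el = etree.SubElement(surg, "step", n=str(step.ordinal))
            if step.narrative:
                narr = etree.SubElement(step_el, "narrative")
                narr.text = etree.CDATA(step.narrative)
            for a in step.annotations:
                _annotation_element(step_el, a)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# Cross-validation against a BA

def validate_record(record: PatientRecord, ba: BasicAnatomy) -> ValidationReport:
    """Cross-check every annotation against the BA; empty report iff valid.

    Biometric length overrides are applied in event order while checking, so
    an interval is judged against the structure's *effective* length at the
    time of its event.  Purely structural problems (unknown ids, bad
    intervals) are reported here; tissue-level conflicts (overlapping
    re-resection, dangling anastomoses) surface when the timeline is
    computed.
    """
    issues: list[ValidationIssue] = []

    def add(rule: str, subject: str, message: str) -> None:
        issues.append(ValidationIssue(rule, subject, message))

    eff_len: dict[str, float] = {sid: s.length_mm for sid, s in ba.structures.items()}
    seen_links: set[str] = set()

    if record.events and record.birth_date > record.events[0].date:
        add("event-before-birth", record.events[0].event_id,
            f"first event {record.events[0].date} precedes birth {record.birth_date}")

    for event in record.events:
        ctx = event.event_id
        for a in event.annotations:
            if isinstance(a, BiometricAnnotation):
                if a.structure_id not in ba.structures:
                    add("unresolved-reference", ctx,
                        f"biometric references unknown structure {a.structure_id!r}")
                    continue
                if a.attribute not in ("length_mm", "diameter_mm"):
                    add("bad-attribute", ctx, f"biometric attribute {a.attribute!r}")
                elif not a.value > 0:
                    add("non-positive-biometric", ctx,
                        f"{a.structure_id} {a.attribute} = {a.value}")
                elif a.attribute == "length_mm":
                    eff_len[a.structure_id] = a.value
            elif isinstance(a, ResectionAnnotation):
                if a.structure_id not in ba.structures:
                    add("unresolved-reference", ctx,
                        f"resection references unknown structure {a.structure_id!r}")
                    continue
                if a.scope == "interval":
                    L = eff_len[a.structure_id]
                    if a.start_mm is None or a.end_mm is None:
                        add("missing-interval", ctx,
                            f"interval resection of {a.structure_id} lacks bounds")
                    elif not (0 <= a.start_mm < a.end_mm <= L):
                        add("interval-out-of-range", ctx,
                            f"[{a.start_mm}, {a.end_mm}) outside [0, {L}) "
                            f"of {a.structure_id}")
                elif a.scope == "whole":
                    if a.start_mm is not None or a.end_mm is not None:
                        add("whole-scope-with-interval", ctx,
                            f"whole resection of {a.structure_id} carries bounds")
                else:
                    add("bad-scope", ctx, f"scope {a.scope!r}")
            else:  # ReconstructionAnnotation
                if a.link_id in seen_links:
                    add("duplicate-link-id", ctx, f"link id {a.link_id!r} reused")
                seen_links.add(a.link_id)
                if a.relation not in RELATIONS:
                    add("unknown-relation", ctx, f"relation {a.relation!r}")
                for end, sid, off in (("from", a.from_id, a.from_offset_mm),
                                      ("to", a.to_id, a.to_offset_mm)):
                    if sid not in ba.structures:
                        add("unresolved-reference", ctx,
                            f"reconstruction {a.link_id} {end} structure {sid!r} unknown")
                    elif not 0 <= off <= eff_len[sid]:
                        add("link-offset-out-of-range", ctx,
                            f"reconstruction {a.link_id} {end} offset {off} outside "
                            f"[0, {eff_len[sid]}] of {sid}")
                if a.length_mm < 0:
                    add("negative-link-length", ctx, f"link {a.link_id} length {a.length_mm}")

    issues.sort(key=lambda i: (i.rule, i.subject, i.message))
    return ValidationReport(tuple(issues))


def extract_deltas(record: PatientRecord) -> list[EventDelta]:
    """Project the machine-readable markup out of a record.

    The result is all that has to be transferred to rebuild the patient's
    model elsewhere: narrative stripped, annotation order preserved.
    Idempotent on content.
    """
    return [
        EventDelta(e.event_id, e.date, e.annotations)
        for e in sorted(record.events, key=_event_key)
    ]
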