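"""Event-sourced patient states: fold surgery deltas over the basic anatomy.

The patient's anatomy at any time is derived, never stored: starting from
the birth state (the BA unmodified), each surgery's annotations are applied
in chronological order, producing one immutable :class:`PatientState` per
event.  A state records, per structure, the *residual* tissue as disjoint
maximal half-open intervals; a structure absent from the map is fully
present, which makes the birth state equal to the BA by construction.

All interval arithmetic is done in exact rational numbers
(:class:`fractions.Fraction`), so the conservation law

    residual length + cumulative resected length = effective length

holds exactly at every timeline point, even under proportional rescaling by
biometric length overrides.

Coordinate convention under overrides: a biometric length override rescales
the structure's whole coordinate system.  Residual intervals, active
artificial-link offsets and the cumulative resected length are rescaled
proportionally (preserving the topology of prior resections); offsets
defined on the BA (attachments, natural-link endpoints, landmarks) are
interpreted through the current scale factor ``effective_length / ba_length``.
Annotations in later events are expressed in current (effective)
coordinates — a surgeon measures the anatomy as it is.

Point containment ("does this point lie on residual tissue?") uses the
*closure* of the residual intervals, so an anastomosis may sit exactly on a
cut end — the typical case.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .anatomy_model import BasicAnatomy, SdmmError
from .markup import (
    Annotation,
    BiometricAnnotation,
    EventDelta,
    PatientRecord,
    ReconstructionAnnotation,
    ResectionAnnotation,
    SurgeryEvent,
)

__all__ = [
    "TimelineError",
    "AnnotationError",
    "ResectionConflictError",
    "DanglingAnastomosisError",
    "BeforeBirthError",
    "ArtificialLink",
    "PatientState",
    "Timeline",
    "ClassLoad",
    "SurgicalLoadSummary",
    "RELATION_CLASS",
    "apply_event",
    "compute_timeline",
    "state_at",
    "surgical_load",
    "reconstruct_from_deltas",
    "check_conservation",
]

logger = logging.getLogger(__name__)

Interval = tuple[Fraction, Fraction]

#: Organ class a link's relation is attributed to in load summaries.
RELATION_CLASS = {
    "luminal": "Intestine",
    "arterial": "Arterial",
    "venous": "Venous",
    "portal": "Portal",
    "biliary": "Biliary",
    "pancreatic": "Pancreatic",
}


class TimelineError(SdmmError):
    """Base for errors raised while applying surgery events."""


class AnnotationError(TimelineError):
    """An annotation is structurally invalid against the current state."""


class ResectionConflictError(TimelineError):
    """A resection overlaps tissue that is already resected."""


class DanglingAnastomosisError(TimelineError):
    """An artificial-link endpoint does not lie on residual tissue."""


class BeforeBirthError(TimelineError):
    """A query date precedes the patient's birth date."""


# ---------------------------------------------------------------------------
# Interval helpers (sorted, disjoint, maximal lists of half-open intervals)

def _merge(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    ivs = sorted((a, b) for a, b in intervals if a < b)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return tuple(out)


def _intersect(intervals: Sequence[Interval], a: Fraction, b: Fraction) -> tuple[Interval, ...]:
    return tuple((max(x, a), min(y, b)) for x, y in intervals
                 if max(x, a) < min(y, b))


def _subtract(intervals: Sequence[Interval], cuts: Sequence[Interval]) -> tuple[Interval, ...]:
    out = list(intervals)
    for ca, cb in cuts:
        nxt: list[Interval] = []
        for a, b in out:
            if cb <= a or b <= ca:
                nxt.append((a, b))
                continue
            if a < ca:
                nxt.append((a, ca))
            if cb < b:
                nxt.append((cb, b))
        out = nxt
    return tuple(out)


def _width(intervals: Sequence[Interval]) -> Fraction:
    return sum((b - a for a, b in intervals), Fraction(0))


def _on_closure(intervals: Sequence[Interval], x: Fraction) -> bool:
    return any(a <= x <= b for a, b in intervals)


# ---------------------------------------------------------------------------
# State types

@dataclass(frozen=True, slots=True)
class ArtificialLink:
    """An active anastomosis, offsets in current effective coordinates."""

    link_id: str
    from_id: str
    from_offset: Fraction
    to_id: str
    to_offset: Fraction
    kind: str
    relation: str
    length: Fraction = Fraction(0)


@dataclass(frozen=True, slots=True)
class PatientState:
    """Derived anatomy at a point in time.  Treat as immutable.

    ``residual`` only lists structures that have been modified; an absent
    structure is fully present as ``[0, effective_length)``.
    """

    ba: BasicAnatomy
    ba_reference: str
    residual: Mapping[str, tuple[Interval, ...]]
    resected: Mapping[str, Fraction]
    links: tuple[ArtificialLink, ...]
    overrides: Mapping[tuple[str, str], Fraction]
    removed_whole: frozenset[str]
    detached: frozenset[str]
    as_of_date: _dt.date

    # -- geometry accessors -------------------------------------------------

    def effective_length(self, sid: str) -> Fraction:
        ov = self.overrides.get((sid, "length_mm"))
        return ov if ov is not None else Fraction(self.ba.structures[sid].length_mm)

    def effective_diameter(self, sid: str) -> Fraction:
        ov = self.overrides.get((sid, "diameter_mm"))
        return ov if ov is not None else Fraction(self.ba.structures[sid].diameter_mm)

    def scale(self, sid: str) -> Fraction:
        """Factor mapping BA offsets on ``sid`` to effective coordinates."""
        return self.effective_length(sid) / Fraction(self.ba.structures[sid].length_mm)

    def residual_intervals(self, sid: str) -> tuple[Interval, ...]:
        got = self.residual.get(sid)
        if got is not None:
            return got
        return ((Fraction(0), self.effective_length(sid)),)

    def residual_width(self, sid: str) -> Fraction:
        return _width(self.residual_intervals(sid))

    def resected_length(self, sid: str) -> Fraction:
        return self.resected.get(sid, Fraction(0))

    def point_on_residual(self, sid: str, offset: Fraction) -> bool:
        return _on_closure(self.residual_intervals(sid), Fraction(offset))

    def find_link(self, link_id: str) -> ArtificialLink | None:
        for l in self.links:
            if l.link_id == link_id:
                return l
        return None


@dataclass(frozen=True, slots=True)
class Timeline:
    """Birth state plus one (event, post-event state) pair per surgery."""

    birth_state: PatientState
    entries: tuple[tuple[SurgeryEvent, PatientState], ...]

    @property
    def final_state(self) -> PatientState:
        return self.entries[-1][1] if self.entries else self.birth_state


@dataclass(frozen=True, slots=True)
class ClassLoad:
    resected_length_mm: float
    whole_structures_removed: int
    artificial_links: int


@dataclass(frozen=True, slots=True)
class SurgicalLoadSummary:
    per_class: Mapping[str, ClassLoad]
    total_surgeries: int


# ---------------------------------------------------------------------------
# Applying annotations

class _Work:
    """Mutable scratch copy of a state while one event is applied."""

    def __init__(self, state: PatientState):
        self.ba = state.ba
        self.residual = dict(state.residual)
        self.resected = dict(state.resected)
        self.links = list(state.links)
        self.overrides = dict(state.overrides)
        self.removed_whole = set(state.removed_whole)
        self.detached = set(state.detached)

    def eff_len(self, sid: str) -> Fraction:
        ov = self.overrides.get((sid, "length_mm"))
        return ov if ov is not None else Fraction(self.ba.structures[sid].length_mm)

    def res_ivs(self, sid: str) -> tuple[Interval, ...]:
        got = self.residual.get(sid)
        if got is not None:
            return got
        return ((Fraction(0), self.eff_len(sid)),)

    # -- annotation application --------------------------------------------

    def _require_structure(self, sid: str, what: str) -> None:
        if sid not in self.ba.structures:
            raise AnnotationError(f"{what} references unknown structure {sid!r}")

    def apply_biometric(self, a: BiometricAnnotation) -> None:
        self._require_structure(a.structure_id, "biometric")
        if a.attribute not in ("length_mm", "diameter_mm"):
            raise AnnotationError(f"unknown biometric attribute {a.attribute!r}")
        value = Fraction(a.value)
        if value <= 0:
            raise AnnotationError(
                f"biometric {a.attribute} of {a.structure_id} must be > 0, got {a.value}")
        sid = a.structure_id
        if a.attribute == "length_mm":
            old = self.eff_len(sid)
            factor = value / old
            if sid in self.residual:
                self.residual[sid] = tuple(
                    (x * factor, y * factor) for x, y in self.residual[sid])
            if sid in self.resected:
                self.resected[sid] = self.resected[sid] * factor
            self.links = [
                replace(l,
                        from_offset=l.from_offset * factor if l.from_id == sid else l.from_offset,
                        to_offset=l.to_offset * factor if l.to_id == sid else l.to_offset)
                for l in self.links
            ]
        self.overrides[(sid, a.attribute)] = value

    def _remove_tissue(self, sid: str, removed: tuple[Interval, ...]) -> None:
        """Subtract intervals from residual; detach children; guard links."""
        if not removed:
            return
        after = _subtract(self.res_ivs(sid), removed)
        # an active anastomosis must not end up floating on removed tissue
        for l in self.links:
            for end_sid, off in ((l.from_id, l.from_offset), (l.to_id, l.to_offset)):
                if end_sid == sid and not _on_closure(after, off):
                    raise DanglingAnastomosisError(
                        f"resection of {sid} would strand anastomosis {l.link_id!r} "
                        f"at offset {float(off)}")
        self.residual[sid] = after
        self.resected[sid] = self.resected.get(sid, Fraction(0)) + _width(removed)
        scale = self.eff_len(sid) / Fraction(self.ba.structures[sid].length_mm)
        for child in self.ba.children_of(sid):
            attach = Fraction(child.attachment_offset_mm) * scale
            if not _on_closure(after, attach):
                self.detached.add(child.id)

    def apply_resection(self, a: ResectionAnnotation, clip_overlaps: bool) -> None:
        self._require_structure(a.structure_id, "resection")
        sid = a.structure_id
        if a.scope == "whole":
            current = self.res_ivs(sid)
            if not current:
                if clip_overlaps:
                    logger.warning("whole resection of %s: already fully resected; skipped", sid)
                    return
                raise ResectionConflictError(
                    f"whole resection of {sid}: structure already fully resected")
            self._remove_tissue(sid, current)
            self.removed_whole.add(sid)
            return
        if a.scope != "interval":
            raise AnnotationError(f"unknown resection scope {a.scope!r}")
        if a.start_mm is None or a.end_mm is None:
            raise AnnotationError(f"interval resection of {sid} lacks bounds")
        s, e = Fraction(a.start_mm), Fraction(a.end_mm)
        L = self.eff_len(sid)
        if not (0 <= s < e <= L):
            raise AnnotationError(
                f"resection [{a.start_mm}, {a.end_mm}) outside [0, {float(L)}) of {sid}")
        current = self.res_ivs(sid)
        inter = _intersect(current, s, e)
        if _width(inter) < e - s:
            if not clip_overlaps:
                raise ResectionConflictError(
                    f"resection [{a.start_mm}, {a.end_mm}) of {sid} overlaps "
                    f"already-resected tissue")
            if not inter:
                logger.warning("resection [%s, %s) of %s lies fully on resected "
                               "tissue; skipped", a.start_mm, a.end_mm, sid)
                return
            logger.warning("resection [%s, %s) of %s clipped to residual tissue",
                           a.start_mm, a.end_mm, sid)
            self._remove_tissue(sid, inter)
        else:
            self._remove_tissue(sid, ((s, e),))

    def apply_reconstruction(self, a: ReconstructionAnnotation) -> None:
        if any(l.link_id == a.link_id for l in self.links):
            raise AnnotationError(f"artificial link id {a.link_id!r} already active")
        for end, sid, off in (("from", a.from_id, a.from_offset_mm),
                              ("to", a.to_id, a.to_offset_mm)):
            self._require_structure(sid, f"reconstruction {a.link_id}")
            x = Fraction(off)
            if not 0 <= x <= self.eff_len(sid):
                raise AnnotationError(
                    f"reconstruction {a.link_id} {end} offset {off} outside "
                    f"[0, {float(self.eff_len(sid))}] of {sid}")
            if not _on_closure(self.res_ivs(sid), x):
                raise DanglingAnastomosisError(
                    f"reconstruction {a.link_id} {end} endpoint at {off} on {sid} "
                    f"lies on resected tissue")
        self.links.append(ArtificialLink(
            a.link_id, a.from_id, Fraction(a.from_offset_mm),
            a.to_id, Fraction(a.to_offset_mm), a.kind, a.relation,
            Fraction(a.length_mm)))


def _apply_annotations(work: _Work, annotations: Iterable[Annotation],
                       clip_overlaps: bool) -> None:
    for a in annotations:
        if isinstance(a, BiometricAnnotation):
            work.apply_biometric(a)
        elif isinstance(a, ResectionAnnotation):
            work.apply_resection(a, clip_overlaps)
        else:
            work.apply_reconstruction(a)


def _finish(work: _Work, state: PatientState, date: _dt.date) -> PatientState:
    return PatientState(
        ba=state.ba,
        ba_reference=state.ba_reference,
        residual=work.residual,
        resected=work.resected,
        links=tuple(work.links),
        overrides=work.overrides,
        removed_whole=frozenset(work.removed_whole),
        detached=frozenset(work.detached),
        as_of_date=date,
    )


def apply_event(state: PatientState, event: SurgeryEvent, *,
                clip_overlaps: bool = False) -> PatientState:
    """Apply one surgery to a state, returning a new state.

    Annotations are applied sequentially in document order, atomically per
    event: an error leaves the input state untouched and nothing partially
    applied.  The input state is never mutated.
    """
    if event.date < state.as_of_date:
        raise TimelineError(
            f"event {event.event_id} dated {event.date} precedes state "
            f"as-of date {state.as_of_date}")
    work = _Work(state)
    _apply_annotations(work, event.annotations, clip_overlaps)
    return _finish(work, state, event.date)


# ---------------------------------------------------------------------------
# Timelines

def birth_state(ba: BasicAnatomy, ba_reference: str,
                birth_date: _dt.date) -> PatientState:
    """The patient's anatomy at birth: the BA without any alteration."""
    return PatientState(ba, ba_reference, {}, {}, (), {}, frozenset(),
                        frozenset(), birth_date)


def compute_timeline(ba: BasicAnatomy, record: PatientRecord, *,
                     clip_overlaps: bool = False) -> Timeline:
    """Fold every event of a record over the birth state, in date order."""
    state = birth_state(ba, record.ba_reference, record.birth_date)
    entries: list[tuple[SurgeryEvent, PatientState]] = []
    for event in sorted(record.events, key=lambda e: (e.date, e.event_id)):
        try:
            state = apply_event(state, event, clip_overlaps=clip_overlaps)
        except TimelineError as exc:
            raise type(exc)(
                f"event {event.event_id} ({event.date}, {event.title!r}): {exc}"
            ) from exc
        entries.append((event, state))
    return Timeline(birth_state(ba, record.ba_reference, record.birth_date),
                    tuple(entries))


def state_at(timeline: Timeline, date: _dt.date) -> PatientState:
    """State after the last event dated on or before ``date``."""
    if date < timeline.birth_state.as_of_date:
        raise BeforeBirthError(
            f"query date {date} precedes birth date {timeline.birth_state.as_of_date}")
    result = timeline.birth_state
    for event, post in timeline.entries:
        if event.date <= date:
            result = post
        else:
            break
    return result


def surgical_load(timeline: Timeline) -> list[SurgicalLoadSummary]:
    """Cumulative surgical-load summary at birth and after each event.

    Per organ class: total resected length (interval widths plus full
    lengths of whole-removed structures all accrue into the per-structure
    resected totals), number of whole structures removed, and number of
    active artificial links, attributed to a class via the link's relation.
    """
    out: list[SurgicalLoadSummary] = []
    states = [timeline.birth_state] + [s for _, s in timeline.entries]
    for k, state in enumerate(states):
        classes = {c.name: [Fraction(0), 0, 0] for c in state.ba.organ_classes}
        for sid, amount in state.resected.items():
            cname = state.ba.structures[sid].organ_class
            classes.setdefault(cname, [Fraction(0), 0, 0])[0] += amount
        for sid in state.removed_whole:
            cname = state.ba.structures[sid].organ_class
            classes.setdefault(cname, [Fraction(0), 0, 0])[1] += 1
        for l in state.links:
            cname = RELATION_CLASS.get(l.relation, l.relation)
            classes.setdefault(cname, [Fraction(0), 0, 0])[2] += 1
        out.append(SurgicalLoadSummary(
            per_class={n: ClassLoad(float(v[0]), v[1], v[2])
                       for n, v in sorted(classes.items())},
            total_surgeries=k,
        ))
    return out


def reconstruct_from_deltas(ba: BasicAnatomy, deltas: Sequence[EventDelta],
                            birth_date: _dt.date, ba_reference: str = "", *,
                            clip_overlaps: bool = False) -> PatientState:
    """Rebuild the cumulative state from transferred markup alone.

    Equals the final state of the full-record timeline: the deltas carry
    everything the model needs, the narrative is only for humans.
    """
    state = birth_state(ba, ba_reference, birth_date)
    for d in sorted(deltas, key=lambda d: (d.date, d.event_id)):
        work = _Work(state)
        try:
            _apply_annotations(work, d.annotations, clip_overlaps)
        except TimelineError as exc:
            raise type(exc)(f"delta {d.event_id} ({d.date}): {exc}") from exc
        state = _finish(work, state, d.date)
    return state


# ---------------------------------------------------------------------------
# Invariant check

def check_conservation(state: PatientState) -> Fraction:
    """Max |residual + resected − effective length| over all structures.

    Exactly zero (a rational 0) for every state this module produces.
    """
    worst = Fraction(0)
    for sid in state.ba.structures:
        diff = abs(state.residual_width(sid) + state.resected_length(sid)
                   - state.effective_length(sid))
        worst = max(worst, diff)
    return worst
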