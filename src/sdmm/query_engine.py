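"""Functional queries on a patient state: lengths, distances, continuity.

Queries run on a *segment graph* derived from the state: nodes are points
``(structure_id, offset)`` on residual tissue, edges are (a) stretches of
residual tissue between consecutive points of interest on one structure,
weighted by arc length, and (b) natural or artificial links of the queried
relation, traversed in flow direction (proximal -> distal within a
structure).  Resected gaps are impassable unless bridged by an artificial
link; an anastomosis has zero intrinsic length unless the annotation says
otherwise.

Distances are shortest traversed length; ties are broken deterministically
by the lexicographically smallest structure-id sequence.  The
``undirected`` flag relaxes flow direction for anatomical (non-functional)
distance.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .anatomy_model import BasicAnatomy, SdmmError, UnknownIdError
from .timeline_engine import PatientState

__all__ = [
    "QueryPoint",
    "PathLeg",
    "LuminalPath",
    "InvalidPointError",
    "residual_length",
    "path_distance",
    "continuity_check",
    "supplying_vessels",
    "resolve_point",
]

Node = tuple[str, Fraction]


class InvalidPointError(SdmmError):
    """A query point does not resolve, or lies on resected tissue."""


@dataclass(frozen=True, slots=True)
class QueryPoint:
    """A point in the anatomy, given one of three ways.

    Exactly one of ``landmark``, ``(structure_id, offset_mm)`` or
    ``link_id`` is set.  A link id resolves to the link's *to* endpoint.
    Landmark offsets are BA coordinates and are rescaled when the structure
    carries a length override.
    """

    landmark: str | None = None
    structure_id: str | None = None
    offset_mm: float | None = None
    link_id: str | None = None

    @classmethod
    def at(cls, structure_id: str, offset_mm: float) -> "QueryPoint":
        return cls(structure_id=structure_id, offset_mm=offset_mm)

    @classmethod
    def at_landmark(cls, name: str) -> "QueryPoint":
        return cls(landmark=name)

    @classmethod
    def at_link(cls, link_id: str) -> "QueryPoint":
        return cls(link_id=link_id)


@dataclass(frozen=True, slots=True)
class PathLeg:
    structure_id: str
    interval_mm: tuple[float, float]  # traversed sub-interval, ordered (lo, hi)
    direction: str                    # "antegrade" | "retrograde"


@dataclass(frozen=True, slots=True)
class LuminalPath:
    legs: tuple[PathLeg, ...]
    total_length_mm: float
    links_crossed: tuple[str, ...]    # natural links as "from->to", artificial by id


def resolve_point(state: PatientState, point: QueryPoint) -> Node:
    """Resolve a query point to ``(structure_id, effective offset)``.

    Raises :class:`InvalidPointError` if it does not resolve or does not
    lie on residual tissue of the state.
    """
    if point.landmark is not None:
        lm = state.ba.landmarks.get(point.landmark)
        if lm is None:
            raise InvalidPointError(f"unknown landmark {point.landmark!r}")
        sid = lm.structure_id
        off = Fraction(lm.offset_mm) * state.scale(sid)
    elif point.link_id is not None:
        link = state.find_link(point.link_id)
        if link is None:
            raise InvalidPointError(f"no active artificial link {point.link_id!r}")
        sid, off = link.to_id, link.to_offset
    else:
        sid = point.structure_id
        if sid not in state.ba.structures:
            raise InvalidPointError(f"unknown structure {sid!r}")
        off = Fraction(point.offset_mm)
        if not 0 <= off <= state.effective_length(sid):
            raise InvalidPointError(
                f"offset {point.offset_mm} outside [0, "
                f"{float(state.effective_length(sid))}] of {sid}")
    if not state.point_on_residual(sid, off):
        raise InvalidPointError(
            f"point ({sid}, {float(off)}) lies on resected tissue")
    return (sid, off)


# ---------------------------------------------------------------------------
# Residual length

def residual_length(state: PatientState, *, structure_ids: Iterable[str] | None = None,
                    organ_class: str | None = None) -> float:
    """Total residual tissue length (mm) over selected structures.

    Select by explicit ids, by organ class, or neither (whole anatomy).
    Biometric overrides are in force.
    """
    if structure_ids is not None:
        ids = list(structure_ids)
        for sid in ids:
            if sid not in state.ba.structures:
                raise UnknownIdError(sid)
    elif organ_class is not None:
        if organ_class not in {c.name for c in state.ba.organ_classes}:
            raise UnknownIdError(organ_class)
        ids = [sid for sid, s in state.ba.structures.items()
               if s.organ_class == organ_class]
    else:
        ids = list(state.ba.structures)
    return float(sum((state.residual_width(sid) for sid in ids), Fraction(0)))


# ---------------------------------------------------------------------------
# Segment graph

def _structure_link_points(state: PatientState, relation: str) -> dict[str, set[Fraction]]:
    """Endpoints of usable links of ``relation``, per structure (eff coords)."""
    pts: dict[str, set[Fraction]] = {}
    for l in state.ba.natural_links:
        if l.relation != relation:
            continue
        pts.setdefault(l.from_id, set()).add(
            Fraction(l.from_offset_mm) * state.scale(l.from_id))
        pts.setdefault(l.to_id, set()).add(
            Fraction(l.to_offset_mm) * state.scale(l.to_id))
    for l in state.links:
        if l.relation != relation:
            continue
        pts.setdefault(l.from_id, set()).add(l.from_offset)
        pts.setdefault(l.to_id, set()).add(l.to_offset)
    return pts


def build_segment_graph(state: PatientState, relation: str, *,
                        undirected: bool = False,
                        extra_points: Sequence[Node] = ()) -> nx.DiGraph:
    """Weighted digraph of residual tissue plus links of one relation.

    Tissue edges run proximal -> distal (offset increasing); link edges run
    in flow direction.  ``undirected`` adds the reverse of every edge.
    Edge data: ``weight`` (Fraction, mm) and ``link`` (None for tissue,
    else a label identifying the link crossed).
    """
    g = nx.DiGraph()
    link_pts = _structure_link_points(state, relation)
    want: dict[str, set[Fraction]] = {sid: set(v) for sid, v in link_pts.items()}
    for sid, off in extra_points:
        want.setdefault(sid, set()).add(Fraction(off))

    for sid, offs in want.items():
        for a, b in state.residual_intervals(sid):
            pts = sorted({a, b} | {x for x in offs if a <= x <= b})
            for x, y in zip(pts, pts[1:]):
                g.add_edge((sid, x), (sid, y), weight=y - x, link=None)
                if undirected:
                    g.add_edge((sid, y), (sid, x), weight=y - x, link=None)

    def on_residual(sid: str, x: Fraction) -> bool:
        return sid in state.ba.structures and state.point_on_residual(sid, x)

    for l in state.ba.natural_links:
        if l.relation != relation:
            continue
        u = (l.from_id, Fraction(l.from_offset_mm) * state.scale(l.from_id))
        v = (l.to_id, Fraction(l.to_offset_mm) * state.scale(l.to_id))
        if on_residual(*u) and on_residual(*v):
            label = f"{l.from_id}->{l.to_id}"
            g.add_edge(u, v, weight=Fraction(0), link=label)
            if undirected:
                g.add_edge(v, u, weight=Fraction(0), link=label)
    for l in state.links:
        if l.relation != relation:
            continue
        u = (l.from_id, l.from_offset)
        v = (l.to_id, l.to_offset)
        if on_residual(*u) and on_residual(*v):
            g.add_edge(u, v, weight=l.length, link=l.link_id)
            if undirected:
                g.add_edge(v, u, weight=l.length, link=l.link_id)
    return g


def _dijkstra_lex(g: nx.DiGraph, source: Node, target: Node):
    """Shortest path by weight; ties broken by lexicographically smallest
    structure-id sequence, then by node sequence (fully deterministic)."""
    if source == target:
        return Fraction(0), [source]
    counter = 0
    heap = [(Fraction(0), (source[0],), counter, source, [source])]
    best: dict[Node, tuple] = {}
    while heap:
        dist, sids, _, node, path = heapq.heappop(heap)
        key = (dist, sids)
        if node in best and best[node] <= key:
            continue
        best[node] = key
        if node == target:
            return dist, path
        for nbr, data in sorted(g[node].items()) if node in g else []:
            ndist = dist + data["weight"]
            nsids = sids if nbr[0] == sids[-1] else sids + (nbr[0],)
            if nbr in best and best[nbr] <= (ndist, nsids):
                continue
            counter += 1
            heapq.heappush(heap, (ndist, nsids, counter, nbr, path + [nbr]))
    return None


def _path_to_luminal(g: nx.DiGraph, nodes: Sequence[Node],
                     total: Fraction) -> LuminalPath:
    legs: list[PathLeg] = []
    links: list[str] = []
    run_sid: str | None = None
    run_start: Fraction | None = None
    run_end: Fraction | None = None

    def flush():
        nonlocal run_sid, run_start, run_end
        if run_sid is not None and run_start != run_end:
            lo, hi = sorted((run_start, run_end))
            direction = "antegrade" if run_end >= run_start else "retrograde"
            legs.append(PathLeg(run_sid, (float(lo), float(hi)), direction))
        run_sid = run_start = run_end = None

    for u, v in zip(nodes, nodes[1:]):
        data = g[u][v]
        if data["link"] is not None:
            flush()
            links.append(data["link"])
            continue
        if run_sid != u[0] or run_end != u[1]:
            flush()
            run_sid, run_start, run_end = u[0], u[1], v[1]
        else:
            run_end = v[1]
    flush()
    return LuminalPath(tuple(legs), float(total), tuple(links))


def path_distance(state: PatientState, frm: QueryPoint, to: QueryPoint,
                  relation: str = "luminal", *,
                  undirected: bool = False) -> LuminalPath | None:
    """Shortest residual-tissue path between two points, or None if
    unreachable.  Points on resected tissue raise
    :class:`InvalidPointError`."""
    a = resolve_point(state, frm)
    b = resolve_point(state, to)
    g = build_segment_graph(state, relation, undirected=undirected,
                            extra_points=(a, b))
    found = _dijkstra_lex(g, a, b)
    if found is None:
        return None
    dist, nodes = found
    return _path_to_luminal(g, nodes, dist)


def continuity_check(state: PatientState, frm: QueryPoint, to: QueryPoint,
                     relation: str = "luminal", *,
                     undirected: bool = False) -> tuple[bool, LuminalPath | None]:
    """Is there functional continuity between two points?  Returns the
    witness path when reachable."""
    path = path_distance(state, frm, to, relation, undirected=undirected)
    return (path is not None), path


def supplying_vessels(state: PatientState, structure_id: str,
                      relation: str = "arterial") -> list[str]:
    """Vessels with a residual-tissue path of ``relation`` ending on the
    structure, traversing links in flow direction.

    A vessel is a structure of the organ class conventionally carrying the
    relation (arterial -> 'Arterial', ...).  Sorted by id.
    """
    if structure_id not in state.ba.structures:
        raise UnknownIdError(structure_id)
    from .timeline_engine import RELATION_CLASS
    vessel_class = RELATION_CLASS.get(relation, relation)
    g = build_segment_graph(state, relation)
    targets = [n for n in g.nodes if n[0] == structure_id]
    rg = g.reverse(copy=False)
    reached: set[str] = set()
    for t in targets:
        for node in nx.descendants(rg, t) | {t}:
            reached.add(node[0])
    return sorted(
        sid for sid in reached
        if state.ba.structures[sid].organ_class == vessel_class
        and sid != structure_id
        and state.residual_width(sid) > 0
    )
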