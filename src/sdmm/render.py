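"""Deterministic schematic rendering: 3D polyline scenes and exports.

The layout is schematic, not anatomically metric in 3D: each structure is a
straight polyline whose *arc length is true to scale*, so on-screen
measurement along a structure is meaningful.  A structure originates at the
point of its parent corresponding to its attachment offset; branch
directions are assigned from a stable hash of the structure id, so equal
models always produce byte-identical exports.

Styling follows the documentation conventions: residual tissue is drawn
solid in its organ-class colour, resected intervals dotted, and artificial
links (reconstructions) as bold green straight segments.

Scenes export to SVG 1.1 (orthographic XY projection), Wavefront OBJ and
glTF 2.0 (JSON with an embedded base64 buffer).  All floats are written
with 3 decimals to guarantee byte determinism.
"""

from __future__ import annotations

import base64
import hashlib
import json
import math
import struct
import datetime as _dt
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .anatomy_model import BasicAnatomy, SdmmError
from .timeline_engine import PatientState, Timeline

__all__ = [
    "CLASS_PALETTE",
    "RECONSTRUCTION_COLOR",
    "ScenePrimitive",
    "Scene",
    "layout_anatomy",
    "render_state",
    "export_scene",
    "render_timeline",
]

#: Fixed colour per organ class; green is reserved for reconstructions.
CLASS_PALETTE = {
    "Arterial": "#c0392b",
    "Venous": "#1f4e9c",
    "Portal": "#6a3d9a",
    "Liver": "#8c510a",
    "Biliary": "#b8860b",
    "Pancreatic": "#e6872e",
    "Intestine": "#555555",
}
_FALLBACK_COLOR = "#888888"
RECONSTRUCTION_COLOR = "#00a000"
RESECTION_COLOR = "#aaaaaa"


@dataclass(frozen=True, slots=True)
class ScenePrimitive:
    points: tuple[tuple[float, float, float], ...]
    style: str       # "solid" | "dotted" | "bold"
    color: str
    source: str      # structure id or link id


@dataclass(frozen=True, slots=True)
class Scene:
    primitives: tuple[ScenePrimitive, ...]
    bbox: tuple[tuple[float, float, float], tuple[float, float, float]]
    metadata: dict


def _bbox(primitives) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    pts = [p for prim in primitives for p in prim.points]
    if not pts:
        return ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
    arr = np.asarray(pts, dtype=float)
    return (tuple(arr.min(axis=0).tolist()), tuple(arr.max(axis=0).tolist()))


def _r3(x: float) -> float:
    return round(float(x) + 0.0, 3)


def _direction(structure_id: str) -> np.ndarray:
    """Stable unit direction from a hash of the id: mostly 'downstream'
    (+y) with a hash-determined azimuth/elevation jitter."""
    h = hashlib.sha256(structure_id.encode("utf-8")).digest()
    azimuth = int.from_bytes(h[:4], "big") / 2**32 * 2 * math.pi
    tilt = (int.from_bytes(h[4:8], "big") / 2**32) * (math.pi / 3)  # 0..60 deg off +y
    d = np.array([
        math.sin(tilt) * math.cos(azimuth),
        math.cos(tilt),
        math.sin(tilt) * math.sin(azimuth),
    ])
    return d / np.linalg.norm(d)


def _layout_geometry(ba: BasicAnatomy) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per structure: (start point, unit direction); BA coordinates in mm."""
    geom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    roots = sorted((s.id for s in ba.roots()))

    def place(sid: str) -> tuple[np.ndarray, np.ndarray]:
        if sid in geom:
            return geom[sid]
        s = ba.structures[sid]
        if s.parent_id is None:
            start = np.array([roots.index(sid) * 400.0, 0.0, 0.0])
        else:
            pstart, pdir = place(s.parent_id)
            start = pstart + pdir * s.attachment_offset_mm
        geom[sid] = (start, _direction(sid))
        return geom[sid]

    for sid in sorted(ba.structures):
        place(sid)
    return geom


def _point_at(geom, ba: BasicAnatomy, state: PatientState | None,
              sid: str, offset) -> tuple[float, float, float]:
    """Map an (effective-coordinate) offset onto the layout polyline."""
    start, direction = geom[sid]
    off = float(offset)
    if state is not None:
        off = float(Fraction(offset) / state.scale(sid))  # back to BA coords
    p = start + direction * off
    return (_r3(p[0]), _r3(p[1]), _r3(p[2]))


def layout_anatomy(ba: BasicAnatomy) -> Scene:
    """Lay out an unmodified BA: one solid polyline per structure."""
    geom = _layout_geometry(ba)
    prims = []
    for sid in sorted(ba.structures):
        s = ba.structures[sid]
        a = _point_at(geom, ba, None, sid, 0.0)
        b = _point_at(geom, ba, None, sid, s.length_mm)
        prims.append(ScenePrimitive(
            (a, b), "solid",
            CLASS_PALETTE.get(s.organ_class, _FALLBACK_COLOR), sid))
    prims_t = tuple(prims)
    return Scene(prims_t, _bbox(prims_t), {"kind": "basic-anatomy"})


def render_state(ba: BasicAnatomy, state: PatientState) -> Scene:
    """Render a patient state over the BA layout.

    Exactly one solid primitive per maximal residual interval, one dotted
    primitive per maximal resected interval, and one bold green primitive
    per active artificial link.
    """
    geom = _layout_geometry(ba)
    prims: list[ScenePrimitive] = []
    for sid in sorted(ba.structures):
        s = ba.structures[sid]
        color = CLASS_PALETTE.get(s.organ_class, _FALLBACK_COLOR)
        eff_len = state.effective_length(sid)
        residual = state.residual_intervals(sid)
        for a, b in residual:
            prims.append(ScenePrimitive(
                (_point_at(geom, ba, state, sid, a),
                 _point_at(geom, ba, state, sid, b)),
                "solid", color, sid))
        resected = []
        cursor = Fraction(0)
        for a, b in residual:
            if cursor < a:
                resected.append((cursor, a))
            cursor = b
        if cursor < eff_len:
            resected.append((cursor, eff_len))
        for a, b in resected:
            prims.append(ScenePrimitive(
                (_point_at(geom, ba, state, sid, a),
                 _point_at(geom, ba, state, sid, b)),
                "dotted", RESECTION_COLOR, sid))
    for link in state.links:
        prims.append(ScenePrimitive(
            (_point_at(geom, ba, state, link.from_id, link.from_offset),
             _point_at(geom, ba, state, link.to_id, link.to_offset)),
            "bold", RECONSTRUCTION_COLOR, link.link_id))
    prims_t = tuple(prims)
    return Scene(prims_t, _bbox(prims_t), {
        "kind": "patient-state",
        "as_of_date": state.as_of_date.isoformat(),
        "patient": state.ba_reference,
    })


# ---------------------------------------------------------------------------
# Exports

def export_scene(scene: Scene, format: str) -> bytes:
    """Export a scene as ``"svg"``, ``"obj"`` or ``"gltf"`` bytes.

    Byte-deterministic for equal scenes.  SVG is an orthographic XY
    projection with styles preserved (dotted via stroke-dasharray, bold via
    stroke-width); OBJ and glTF carry the full 3D polylines.
    """
    fmt = format.lower()
    if fmt == "svg":
        return _export_svg(scene)
    if fmt == "obj":
        return _export_obj(scene)
    if fmt in ("gltf", "gltf2"):
        return _export_gltf(scene)
    raise SdmmError(f"unknown export format {format!r} (svg, obj, gltf)")


def _f(x: float) -> str:
    return f"{float(x):.3f}"


def _export_svg(scene: Scene) -> bytes:
    (x0, y0, _), (x1, y1, _) = scene.bbox
    pad = 20.0
    w = max(x1 - x0, 1.0) + 2 * pad
    h = max(y1 - y0, 1.0) + 2 * pad
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{_f(x0 - pad)} {_f(-y1 - pad)} {_f(w)} {_f(h)}">',
    ]
    for prim in scene.primitives:
        pts = " ".join(f"{_f(p[0])},{_f(-p[1])}" for p in prim.points)
        style = f'fill="none" stroke="{prim.color}"'
        if prim.style == "dotted":
            style += ' stroke-width="1.5" stroke-dasharray="4 3"'
        elif prim.style == "bold":
            style += ' stroke-width="4"'
        else:
            style += ' stroke-width="1.5"'
        lines.append(f'  <polyline class="prim {prim.style}" '
                     f'data-source="{prim.source}" points="{pts}" {style}/>')
    lines.append("</svg>")
    return ("\n".join(lines) + "\n").encode("utf-8")


def _export_obj(scene: Scene) -> bytes:
    lines = ["# schematic anatomy scene"]
    index = 1
    for prim in scene.primitives:
        lines.append(f"o {prim.source}.{prim.style}")
        for p in prim.points:
            lines.append(f"v {_f(p[0])} {_f(p[1])} {_f(p[2])}")
        idx = " ".join(str(index + i) for i in range(len(prim.points)))
        lines.append(f"l {idx}")
        index += len(prim.points)
    return ("\n".join(lines) + "\n").encode("utf-8")


def _export_gltf(scene: Scene) -> bytes:
    buffer = bytearray()
    accessors = []
    buffer_views = []
    meshes = []
    nodes = []
    for i, prim in enumerate(scene.primitives):
        pts = [(float(_f(x)), float(_f(y)), float(_f(z))) for x, y, z in prim.points]
        raw = b"".join(struct.pack("<fff", *p) for p in pts)
        offset = len(buffer)
        buffer.extend(raw)
        buffer_views.append({"buffer": 0, "byteOffset": offset, "byteLength": len(raw)})
        mins = [min(p[k] for p in pts) for k in range(3)]
        maxs = [max(p[k] for p in pts) for k in range(3)]
        accessors.append({
            "bufferView": i, "componentType": 5126, "count": len(pts),
            "type": "VEC3", "min": mins, "max": maxs,
        })
        meshes.append({
            "name": f"{prim.source}.{prim.style}",
            "primitives": [{"attributes": {"POSITION": i}, "mode": 3}],
            "extras": {"style": prim.style, "color": prim.color,
                       "source": prim.source},
        })
        nodes.append({"mesh": i, "name": f"{prim.source}.{prim.style}"})
    doc = {
        "asset": {"version": "2.0", "generator": "sdmm"},
        "scene": 0,
        "scenes": [{"nodes": list(range(len(nodes)))}],
        "nodes": nodes,
        "meshes": meshes,
        "accessors": accessors,
        "bufferViews": buffer_views,
        "buffers": [{
            "byteLength": len(buffer),
            "uri": "data:application/octet-stream;base64,"
                   + base64.b64encode(bytes(buffer)).decode("ascii"),
        }],
    }
    if not scene.primitives:
        for key in ("nodes", "meshes", "accessors", "bufferViews", "buffers"):
            doc.pop(key)
        doc["scenes"] = [{"nodes": []}]
    return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode("utf-8")


# ---------------------------------------------------------------------------
# Timeline rendering

def render_timeline(timeline: Timeline, birth_date: _dt.date | None = None) -> bytes:
    """Render a surgical timeline as SVG.

    Horizontal axis from birth to the last event, with one gridline per
    completed decade of patient age and one labelled flag per surgery; the
    birth-state schematic sits on the left, the cumulative (current) state
    on the right.
    """
    birth = birth_date or timeline.birth_state.as_of_date
    events = [e for e, _ in timeline.entries]
    last_date = events[-1].date if events else birth
    span_days = max((last_date - birth).days, 1)

    width, height, margin = 1000.0, 360.0, 60.0
    axis_y = height - 80.0
    axis_w = width - 2 * margin

    def x_at(date: _dt.date) -> float:
        return margin + (date - birth).days / span_days * axis_w

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="0 0 {_f(width)} {_f(height)}">',
        f'  <line class="axis" x1="{_f(margin)}" y1="{_f(axis_y)}" '
        f'x2="{_f(margin + axis_w)}" y2="{_f(axis_y)}" stroke="#000" stroke-width="2"/>',
    ]
    # the timeline is divided into decades of patient age
    last_age_years = int((last_date.year - birth.year)
                         - ((last_date.month, last_date.day) < (birth.month, birth.day)))
    for decade in range(10, last_age_years + 1, 10):
        try:
            gdate = birth.replace(year=birth.year + decade)
        except ValueError:  # Feb 29
            gdate = birth.replace(year=birth.year + decade, day=28)
        gx = x_at(gdate)
        lines.append(f'  <line class="decade" x1="{_f(gx)}" y1="{_f(axis_y - 160)}" '
                     f'x2="{_f(gx)}" y2="{_f(axis_y + 10)}" '
                     f'stroke="#ccc" stroke-width="1"/>')
        lines.append(f'  <text class="decade-label" x="{_f(gx)}" '
                     f'y="{_f(axis_y + 26)}" font-size="11" '
                     f'text-anchor="middle">{decade}y</text>')
    for event in events:
        fx = x_at(event.date)
        lines.append(f'  <g class="flag" data-event="{event.event_id}">')
        lines.append(f'    <line x1="{_f(fx)}" y1="{_f(axis_y - 40)}" '
                     f'x2="{_f(fx)}" y2="{_f(axis_y)}" stroke="#c0392b" '
                     f'stroke-width="2"/>')
        lines.append(f'    <circle cx="{_f(fx)}" cy="{_f(axis_y - 44)}" r="5" '
                     f'fill="#c0392b"/>')
        lines.append(f'    <text x="{_f(fx)}" y="{_f(axis_y - 54)}" font-size="10" '
                     f'text-anchor="middle">{event.date.isoformat()}</text>')
        lines.append('  </g>')

    def thumbnail(state: PatientState, cx: float, label: str) -> None:
        scene = render_state(state.ba, state)
        (bx0, by0, _), (bx1, by1, _) = scene.bbox
        sw = max(bx1 - bx0, 1.0)
        sh = max(by1 - by0, 1.0)
        size = 180.0
        s = min(size / sw, size / sh)
        lines.append(f'  <g class="thumbnail" data-kind="{label}" transform='
                     f'"translate({_f(cx)},{_f(30.0)}) scale({_f(s)},{_f(-s)}) '
                     f'translate({_f(-bx0)},{_f(-by1)})">')
        for prim in scene.primitives:
            pts = " ".join(f"{_f(p[0])},{_f(p[1])}" for p in prim.points)
            dash = ' stroke-dasharray="4 3"' if prim.style == "dotted" else ""
            swidth = 4 if prim.style == "bold" else 1.5
            lines.append(f'    <polyline points="{pts}" fill="none" '
                         f'stroke="{prim.color}" stroke-width="{_f(swidth / s)}"{dash}/>')
        lines.append('  </g>')

    thumbnail(timeline.birth_state, margin, "birth")
    thumbnail(timeline.final_state, margin + axis_w - 180.0, "current")
    lines.append("</svg>")
    return ("\n".join(lines) + "\n").encode("utf-8")
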