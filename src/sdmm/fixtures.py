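"""Packaged reference models: digestive BA, cases P1/P2, random generator.

The digestive basic anatomy covers the seven functional organ classes
relevant to visceral surgery — Arterial, Venous, Portal, Liver, Biliary,
Pancreatic, Intestine — with the full luminal chain from esophagus to
rectum, a schematic biliary tree, pancreas, and the major splanchnic
vessels.  Lengths and diameters are textbook defaults in integer
millimetres (e.g. small intestine about 5 m in total); they are documented
conventions, not measured values.

P1 and P2 are two simulated patients with five visceral surgeries each;
their annotation details (exact intervals, anastomosis positions) are a
clinical concretization of the named procedures, commented inline.

:func:`generate_random_case` drives property tests: it simulates the
patient state forward while drawing annotations so every generated record
replays without conflicts.  All coordinates are integer millimetres, which
keeps the 1-mm discretization oracle exact.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np

from .anatomy_model import (
    AnatomicalStructure,
    BasicAnatomy,
    Landmark,
    NaturalLink,
    OrganClass,
    SdmmError,
    load_basic_anatomy,
    write_basic_anatomy,
)
from .markup import (
    BiometricAnnotation,
    PatientRecord,
    ReconstructionAnnotation,
    ResectionAnnotation,
    SurgeryEvent,
    SurgicalStep,
    read_patient_record,
)
from .timeline_engine import TimelineError, apply_event, birth_state

__all__ = [
    "BA_REFERENCE",
    "STRUCTURE_SETS",
    "CaseSpec",
    "GenerationError",
    "make_basic_anatomy_digestive",
    "make_case_P1",
    "make_case_P2",
    "generate_random_case",
    "load_fixture_ba",
    "load_fixture_record",
]

BA_REFERENCE = "digestive-ba-v1"

#: Named structure sets for residual-length queries.  ``small_intestine``
#: includes the duodenum (anatomical convention: duodenum + jejunum + ileum).
STRUCTURE_SETS = {
    "small_intestine": ("duodenum", "jejunum", "ileum"),
    "colon": ("cecum", "ascending_colon", "transverse_colon",
              "descending_colon", "sigmoid_colon"),
    "foregut": ("esophagus", "stomach", "duodenum"),
}


class GenerationError(SdmmError):
    """The random-case generator could not satisfy its spec."""


def _s(id, name, cls, parent=None, at=0, length=1, diam=0):
    return AnatomicalStructure(id, name, cls, parent, float(at), float(length),
                               float(diam))


def make_basic_anatomy_digestive() -> BasicAnatomy:
    """Build the packaged digestive BA (integer-mm biometrics)."""
    classes = tuple(OrganClass(n) for n in (
        "Arterial", "Venous", "Portal", "Liver", "Biliary", "Pancreatic",
        "Intestine"))

    structures = [
        # Intestine: the luminal chain, each segment originating at the
        # distal end of the previous one
        _s("esophagus", "Esophagus", "Intestine", length=250, diam=20),
        _s("stomach", "Stomach", "Intestine", "esophagus", 250, 250, 80),
        _s("duodenum", "Duodenum", "Intestine", "stomach", 250, 260, 30),
        _s("jejunum", "Jejunum", "Intestine", "duodenum", 260, 2000, 28),
        _s("ileum", "Ileum", "Intestine", "jejunum", 2000, 3000, 25),
        _s("cecum", "Cecum", "Intestine", "ileum", 3000, 60, 70),
        _s("appendix", "Vermiform appendix", "Intestine", "cecum", 30, 90, 7),
        _s("ascending_colon", "Ascending colon", "Intestine", "cecum", 60, 150, 55),
        _s("transverse_colon", "Transverse colon", "Intestine",
           "ascending_colon", 150, 450, 50),
        _s("descending_colon", "Descending colon", "Intestine",
           "transverse_colon", 450, 250, 45),
        _s("sigmoid_colon", "Sigmoid colon", "Intestine",
           "descending_colon", 250, 400, 40),
        _s("rectum", "Rectum", "Intestine", "sigmoid_colon", 400, 150, 40),
        # Liver
        _s("liver", "Liver", "Liver", length=150, diam=120),
        # Biliary: offset 0 of the cystic duct is its gallbladder end
        _s("common_bile_duct", "Common bile duct", "Biliary", length=80, diam=8),
        _s("cystic_duct", "Cystic duct", "Biliary", "common_bile_duct", 20, 40, 4),
        _s("gallbladder", "Gallbladder", "Biliary", "cystic_duct", 0, 80, 35),
        # Pancreatic: offset 0 at the tail, the head adjoins the duodenum
        _s("pancreas", "Pancreas", "Pancreatic", length=150, diam=30),
        # Arterial
        _s("abdominal_aorta", "Abdominal aorta", "Arterial", length=200, diam=25),
        _s("celiac_trunk", "Celiac trunk", "Arterial", "abdominal_aorta", 50, 30, 9),
        _s("common_hepatic_artery", "Common hepatic artery", "Arterial",
           "celiac_trunk", 30, 50, 6),
        _s("left_gastric_artery", "Left gastric artery", "Arterial",
           "celiac_trunk", 30, 40, 4),
        _s("splenic_artery", "Splenic artery", "Arterial", "celiac_trunk", 30, 60, 6),
        _s("superior_mesenteric_artery", "Superior mesenteric artery", "Arterial",
           "abdominal_aorta", 80, 120, 8),
        _s("inferior_mesenteric_artery", "Inferior mesenteric artery", "Arterial",
           "abdominal_aorta", 150, 80, 5),
        # Venous: the SMV is classified under the systemic venous tree so a
        # venous-class resection can document portal-confluence surgery; its
        # functional drainage runs over a portal-relation link below
        _s("inferior_vena_cava", "Inferior vena cava", "Venous", length=250, diam=22),
        _s("hepatic_vein", "Hepatic vein", "Venous", "inferior_vena_cava", 180, 40, 10),
        _s("superior_mesenteric_vein", "Superior mesenteric vein", "Venous",
           "inferior_vena_cava", 100, 100, 10),
        # Portal
        _s("portal_vein", "Portal vein", "Portal", length=80, diam=12),
        _s("splenic_vein", "Splenic vein", "Portal", "portal_vein", 0, 80, 8),
    ]

    def link(frm, foff, to, toff, rel):
        return NaturalLink(frm, float(foff), to, float(toff), rel)

    links = [
        # stool propulsion, proximal to distal
        link("esophagus", 250, "stomach", 0, "luminal"),
        link("stomach", 250, "duodenum", 0, "luminal"),
        link("duodenum", 260, "jejunum", 0, "luminal"),
        link("jejunum", 2000, "ileum", 0, "luminal"),
        link("ileum", 3000, "cecum", 0, "luminal"),
        link("cecum", 30, "appendix", 0, "luminal"),   # blind-ending
        link("cecum", 60, "ascending_colon", 0, "luminal"),
        link("ascending_colon", 150, "transverse_colon", 0, "luminal"),
        link("transverse_colon", 450, "descending_colon", 0, "luminal"),
        link("descending_colon", 250, "sigmoid_colon", 0, "luminal"),
        link("sigmoid_colon", 400, "rectum", 0, "luminal"),
        # bile flow
        link("liver", 75, "common_bile_duct", 0, "biliary"),
        link("gallbladder", 0, "cystic_duct", 0, "biliary"),
        link("cystic_duct", 40, "common_bile_duct", 20, "biliary"),
        link("common_bile_duct", 80, "duodenum", 200, "biliary"),
        # pancreatic juice
        link("pancreas", 150, "duodenum", 200, "pancreatic"),
        # arterial blood flow
        link("abdominal_aorta", 50, "celiac_trunk", 0, "arterial"),
        link("celiac_trunk", 30, "common_hepatic_artery", 0, "arterial"),
        link("celiac_trunk", 30, "left_gastric_artery", 0, "arterial"),
        link("celiac_trunk", 30, "splenic_artery", 0, "arterial"),
        link("abdominal_aorta", 80, "superior_mesenteric_artery", 0, "arterial"),
        link("abdominal_aorta", 150, "inferior_mesenteric_artery", 0, "arterial"),
        link("common_hepatic_artery", 50, "liver", 0, "arterial"),
        link("common_hepatic_artery", 25, "duodenum", 130, "arterial"),
        link("left_gastric_artery", 40, "stomach", 100, "arterial"),
        link("left_gastric_artery", 40, "esophagus", 200, "arterial"),
        link("splenic_artery", 60, "pancreas", 75, "arterial"),
        link("superior_mesenteric_artery", 20, "pancreas", 120, "arterial"),
        link("superior_mesenteric_artery", 40, "jejunum", 1000, "arterial"),
        link("superior_mesenteric_artery", 60, "ileum", 1500, "arterial"),
        link("superior_mesenteric_artery", 80, "cecum", 30, "arterial"),
        link("superior_mesenteric_artery", 90, "appendix", 45, "arterial"),
        link("superior_mesenteric_artery", 100, "ascending_colon", 75, "arterial"),
        link("superior_mesenteric_artery", 110, "transverse_colon", 200, "arterial"),
        link("inferior_mesenteric_artery", 40, "descending_colon", 125, "arterial"),
        link("inferior_mesenteric_artery", 60, "sigmoid_colon", 200, "arterial"),
        link("inferior_mesenteric_artery", 80, "rectum", 75, "arterial"),
        # venous / portal drainage
        link("superior_mesenteric_vein", 100, "portal_vein", 0, "portal"),
        link("splenic_vein", 80, "portal_vein", 0, "portal"),
        link("portal_vein", 80, "liver", 0, "portal"),
        link("liver", 150, "hepatic_vein", 0, "venous"),
        link("hepatic_vein", 40, "inferior_vena_cava", 180, "venous"),
    ]

    landmarks = {
        "esophageal_inlet": Landmark("esophageal_inlet", "esophagus", 0.0),
        "ligament_of_treitz": Landmark("ligament_of_treitz", "jejunum", 0.0),
        "ileocecal_valve": Landmark("ileocecal_valve", "ileum", 3000.0),
        "rectum_distal": Landmark("rectum_distal", "rectum", 150.0),
        "papilla_vateri": Landmark("papilla_vateri", "duodenum", 200.0),
    }

    return BasicAnatomy(classes, {s.id: s for s in structures}, tuple(links),
                        landmarks)


# ---------------------------------------------------------------------------
# Simulated patients

def _event(eid, date, title, *steps):
    return SurgeryEvent(eid, _dt.date.fromisoformat(date), title, tuple(
        SurgicalStep(i + 1, narrative, tuple(annots))
        for i, (narrative, annots) in enumerate(steps)))


def _resect(sid, start=None, end=None):
    if start is None:
        return ResectionAnnotation(sid, "whole")
    return ResectionAnnotation(sid, "interval", float(start), float(end))


def make_case_P1() -> PatientRecord:
    """Simulated patient P1: five surgeries, two without anatomical change.

    Appendectomy; two relaparotomies with adhesiolysis only; left
    hemicolectomy; esophageal resection with gastric sleeve and
    gastroesophagostomy.
    """
    events = (
        _event("e1", "1988-06-14", "Appendectomy",
               ("Laparotomy, ligation of the appendix base, appendectomy.",
                [_resect("appendix")])),
        # adhesiolysis divides adhesions only: no modelled anatomy changes
        _event("e2", "1992-09-03", "Relaparotomy with adhesiolysis",
               ("Extensive adhesiolysis; bowel intact, no resection.", [])),
        _event("e3", "1995-02-20", "Relaparotomy with adhesiolysis",
               ("Recurrent adhesions divided sharply; no resection.", [])),
        _event("e4", "2005-11-08", "Left hemicolectomy",
               ("Mobilization of the splenic flexure, resection of the "
                "distal transverse colon, the descending colon and the "
                "proximal sigmoid; transverse-sigmoid anastomosis.",
                [_resect("transverse_colon", 300, 450),
                 _resect("descending_colon"),
                 _resect("sigmoid_colon", 0, 100),
                 ReconstructionAnnotation(
                     "al_p1_colo", "transverse_colon", 300.0,
                     "sigmoid_colon", 100.0, "colocolostomy", "luminal")])),
        _event("e5", "2014-05-27",
               "Esophageal resection with gastric sleeve",
               ("Subtotal esophagectomy for distal esophageal carcinoma.",
                [_resect("esophagus", 100, 250)]),
               ("Formation of a gastric sleeve conduit; "
                "cervical gastroesophagostomy.",
                [BiometricAnnotation("stomach", "diameter_mm", 40.0),
                 ReconstructionAnnotation(
                     "al_p1_ge", "esophagus", 100.0, "stomach", 0.0,
                     "gastroesophagostomy", "luminal")])),
    )
    return PatientRecord("P1", _dt.date(1955, 3, 10), BA_REFERENCE, events)


def make_case_P2() -> PatientRecord:
    """Simulated patient P2: five surgeries with cumulative bowel loss.

    Cholecystectomy; ileocecal resection; ileum segment resection; left
    hemicolectomy; pancreatic head resection with partial resection of the
    superior mesenteric vein.
    """
    events = (
        _event("e1", "1985-04-11", "Cholecystectomy",
               ("Laparoscopic cholecystectomy; the cystic duct is clipped "
                "and divided, the gallbladder removed.",
                [_resect("gallbladder"), _resect("cystic_duct")])),
        _event("e2", "1998-08-23", "Ileocecal resection",
               ("Resection of the terminal ileum and cecum including the "
                "appendix; ileo-ascending anastomosis.",
                [_resect("ileum", 2800, 3000),
                 _resect("appendix"),
                 _resect("cecum"),
                 ReconstructionAnnotation(
                     "al_p2_ileocol", "ileum", 2800.0,
                     "ascending_colon", 0.0, "ileocolostomy", "luminal")])),
        _event("e3", "2005-03-30", "Relaparotomy, ileum segment resection",
               ("Segmental resection of a strictured mid-ileum loop; "
                "end-to-end ileoileostomy.",
                [_resect("ileum", 1500, 1900),
                 ReconstructionAnnotation(
                     "al_p2_ileo", "ileum", 1500.0, "ileum", 1900.0,
                     "ileoileostomy", "luminal")])),
        _event("e4", "2013-10-05", "Left hemicolectomy",
               ("Oncologic left hemicolectomy for colon carcinoma; "
                "transverse-sigmoid anastomosis.",
                [_resect("transverse_colon", 300, 450),
                 _resect("descending_colon"),
                 _resect("sigmoid_colon", 0, 100),
                 ReconstructionAnnotation(
                     "al_p2_colo", "transverse_colon", 300.0,
                     "sigmoid_colon", 100.0, "colocolostomy", "luminal")])),
        _event("e5", "2020-06-18",
               "Pancreatic head resection with partial SMV resection",
               ("Duodenum-preserving resection of the pancreatic head for "
                "carcinoma with en-bloc partial resection of the infiltrated "
                "superior mesenteric vein.",
                [_resect("pancreas", 100, 150),
                 _resect("superior_mesenteric_vein", 40, 70)]),
               ("Venous end-to-end reconstruction; pancreaticojejunostomy "
                "of the remnant.",
                [ReconstructionAnnotation(
                     "al_p2_smv", "superior_mesenteric_vein", 40.0,
                     "superior_mesenteric_vein", 70.0,
                     "venous end-to-end anastomosis", "venous"),
                 ReconstructionAnnotation(
                     "al_p2_pj", "pancreas", 100.0, "jejunum", 600.0,
                     "pancreaticojejunostomy", "pancreatic")])),
    )
    return PatientRecord("P2", _dt.date(1960, 7, 1), BA_REFERENCE, events)


# ---------------------------------------------------------------------------
# Packaged XML fixtures

def load_fixture_ba() -> BasicAnatomy:
    """Load the packaged digestive BA XML document."""
    data = resources.files("sdmm").joinpath(
        "data/basic_anatomy_digestive.xml").read_bytes()
    return load_basic_anatomy(data)


def load_fixture_record(case: str) -> PatientRecord:
    """Load a packaged case document ("P1" or "P2")."""
    name = {"P1": "case_p1.xml", "P2": "case_p2.xml"}.get(case.upper())
    if name is None:
        raise SdmmError(f"unknown fixture case {case!r} (P1, P2)")
    data = resources.files("sdmm").joinpath(f"data/{name}").read_bytes()
    return read_patient_record(data)


# ---------------------------------------------------------------------------
# Random case generator

@dataclass(frozen=True, slots=True)
class CaseSpec:
    """Parameters of a seeded synthetic patient case.

    Per-event probabilities say how likely each annotation kind appears in
    an event; an event drawing none of them is an adhesiolysis-like
    procedure.  Interval widths are drawn uniformly (integer mm).
    """

    seed: int
    n_surgeries: int = 5
    p_resection: float = 0.7
    p_reconstruction: float = 0.35
    p_biometric: float = 0.15
    p_whole: float = 0.2
    interval_width_mm: tuple[int, int] = (20, 400)
    birth_date: _dt.date = _dt.date(1960, 1, 1)

    def __post_init__(self):
        for p in (self.p_resection, self.p_reconstruction, self.p_biometric,
                  self.p_whole):
            if not 0 <= p <= 1:
                raise GenerationError(f"probability {p} outside [0, 1]")
        if self.n_surgeries < 0:
            raise GenerationError("n_surgeries must be >= 0")


_RETRIES = 50


def _integer_points(intervals, min_width=0):
    """Residual intervals wide enough, with integer candidate positions."""
    out = []
    for a, b in intervals:
        lo = int(-(-a // 1))  # ceil
        hi = int(b // 1)
        if hi - lo >= min_width:
            out.append((lo, hi))
    return out


def generate_random_case(spec: CaseSpec, ba: BasicAnatomy) -> PatientRecord:
    """Generate a reproducible patient record valid against ``ba``.

    The generator simulates the timeline forward, so every annotation is
    valid against the residual tissue at its event and replaying the record
    never raises a conflict.  Equal seeds give identical records.
    """
    rng = np.random.default_rng(spec.seed)
    state = birth_state(ba, BA_REFERENCE, spec.birth_date)
    sids = sorted(ba.structures)
    link_seq = 0
    events = []
    day = spec.birth_date + _dt.timedelta(days=int(rng.integers(6000, 14000)))

    # structures safe for a length override: untouched, no active links on
    # them, and every BA-referenced offset stays integer after rescaling
    referenced: dict[str, set[int]] = {sid: set() for sid in sids}
    for s in ba.structures.values():
        if s.parent_id is not None:
            referenced[s.parent_id].add(int(s.attachment_offset_mm))
    for l in ba.natural_links:
        referenced[l.from_id].add(int(l.from_offset_mm))
        referenced[l.to_id].add(int(l.to_offset_mm))
    for lm in ba.landmarks.values():
        referenced[lm.structure_id].add(int(lm.offset_mm))

    def try_apply(ann) -> bool:
        nonlocal state
        probe = SurgeryEvent("probe", day, "", (SurgicalStep(1, "", (ann,)),))
        try:
            state = apply_event(state, probe)
            return True
        except TimelineError:
            return False

    def draw_resection():
        for _ in range(_RETRIES):
            sid = sids[int(rng.integers(len(sids)))]
            ivs = _integer_points(state.residual_intervals(sid), 10)
            if not ivs:
                continue
            if rng.random() < spec.p_whole:
                ann = _resect(sid)
            else:
                lo, hi = ivs[int(rng.integers(len(ivs)))]
                wmin, wmax = spec.interval_width_mm
                width = int(rng.integers(max(wmin, 5),
                                         max(min(wmax, hi - lo), wmin, 5) + 1))
                width = min(width, hi - lo)
                start = int(rng.integers(lo, hi - width + 1))
                ann = _resect(sid, start, start + width)
            if try_apply(ann):
                return ann
        raise GenerationError("could not place a resection: no residual "
                              "tissue satisfies the spec")

    def draw_reconstruction():
        nonlocal link_seq
        for _ in range(_RETRIES):
            relation = "luminal" if rng.random() < 0.8 else str(
                rng.choice(["arterial", "venous", "portal", "biliary",
                            "pancreatic"]))
            picks = []
            for _ in range(2):
                sid = sids[int(rng.integers(len(sids)))]
                ivs = _integer_points(state.residual_intervals(sid), 1)
                if not ivs:
                    break
                lo, hi = ivs[int(rng.integers(len(ivs)))]
                picks.append((sid, int(rng.integers(lo, hi + 1))))
            if len(picks) < 2 or picks[0] == picks[1]:
                continue
            link_seq += 1
            ann = ReconstructionAnnotation(
                f"al{link_seq}", picks[0][0], float(picks[0][1]),
                picks[1][0], float(picks[1][1]), "anastomosis", relation)
            if try_apply(ann):
                return ann
            link_seq -= 1
        return None

    def draw_biometric():
        for _ in range(_RETRIES):
            sid = sids[int(rng.integers(len(sids)))]
            if rng.random() < 0.7:
                ann = BiometricAnnotation(sid, "diameter_mm",
                                          float(int(rng.integers(2, 101))))
                if try_apply(ann):
                    return ann
                continue
            # length override: only on untouched structures, keeping every
            # referenced offset integer under the rescaling
            if sid in state.residual or (sid, "length_mm") in state.overrides:
                continue
            if any(sid in (l.from_id, l.to_id) for l in state.links):
                continue
            L0 = int(ba.structures[sid].length_mm)
            for _ in range(20):
                L1 = int(rng.integers(max(int(L0 * 0.6), 5), int(L0 * 1.6) + 1))
                if L1 != L0 and all(o * L1 % L0 == 0 for o in referenced[sid]):
                    ann = BiometricAnnotation(sid, "length_mm", float(L1))
                    if try_apply(ann):
                        return ann
                    break
        return None

    for k in range(spec.n_surgeries):
        annots = []
        if rng.random() < spec.p_biometric:
            a = draw_biometric()
            if a is not None:
                annots.append(a)
        if rng.random() < spec.p_resection:
            annots.append(draw_resection())
            if rng.random() < 0.3:
                annots.append(draw_resection())
        if rng.random() < spec.p_reconstruction:
            a = draw_reconstruction()
            if a is not None:
                annots.append(a)
        title = "Laparotomy" if annots else "Relaparotomy with adhesiolysis"
        narrative = (f"Synthetic procedure {k + 1} with "
                     f"{len(annots)} annotation(s).")
        events.append(SurgeryEvent(
            f"e{k + 1}", day, title,
            (SurgicalStep(1, narrative, tuple(annots)),)))
        day = day + _dt.timedelta(days=int(rng.integers(120, 3000)))

    return PatientRecord(f"R{spec.seed}", spec.birth_date, BA_REFERENCE,
                         tuple(events))
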