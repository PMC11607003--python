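import datetime as dt

import pytest

import oracle_mm
from conftest import random_cases
from sdmm.markup import (
    PatientRecord,
    ReconstructionAnnotation,
    ResectionAnnotation,
    SurgeryEvent,
    SurgicalStep,
)
from sdmm.anatomy_model import (
    AnatomicalStructure,
    BasicAnatomy,
    NaturalLink,
    OrganClass,
)
from sdmm.query_engine import (
    InvalidPointError,
    QueryPoint,
    continuity_check,
    path_distance,
    residual_length,
    resolve_point,
    supplying_vessels,
)
from sdmm.fixtures import STRUCTURE_SETS
from sdmm.timeline_engine import apply_event, birth_state, compute_timeline


def _event(eid, date, *annots):
    return SurgeryEvent(eid, dt.date.fromisoformat(date), "Op",
                        (SurgicalStep(1, "", tuple(annots)),))


def _resect(sid, start=None, end=None):
    if start is None:
        return ResectionAnnotation(sid, "whole")
    return ResectionAnnotation(sid, "interval", float(start), float(end))


@pytest.fixture
def birth(ba):
    return birth_state(ba, "digestive-ba-v1", dt.date(1960, 1, 1))


class TestResidualLength:
    def test_birth_small_intestine_is_fixture_sum(self, birth):
        value = residual_length(birth,
                                structure_ids=STRUCTURE_SETS["small_intestine"])
        assert value == 260 + 2000 + 3000

    def test_resection_subtracts_exactly_its_width(self, birth):
        post = apply_event(birth, _event("e1", "1990-01-01",
                                         _resect("ileum", 700, 800)))
        before = residual_length(birth, organ_class="Intestine")
        after = residual_length(post, organ_class="Intestine")
        assert before - after == 100

    def test_matches_cell_count_oracle_on_random_states(self, ba):
        for record in random_cases(ba, 10, seed0=400):
            state = compute_timeline(ba, record).final_state
            ids = sorted(ba.structures)
            assert residual_length(state, structure_ids=ids) == \
                oracle_mm.oracle_residual_length(state, ids)

    def test_unknown_selector_raises(self, birth):
        with pytest.raises(KeyError):
            residual_length(birth, structure_ids=["nope"])
        with pytest.raises(KeyError):
            residual_length(birth, organ_class="Nope")


class TestPathDistance:
    def test_point_to_itself_is_zero(self, birth):
        p = QueryPoint.at("jejunum", 500.0)
        path = path_distance(birth, p, p)
        assert path.total_length_mm == 0.0 and path.legs == ()

    def test_treitz_to_point_350mm_distal_is_arc_length(self, birth):
        path = path_distance(birth, QueryPoint.at_landmark("ligament_of_treitz"),
                             QueryPoint.at("jejunum", 350.0))
        assert path.total_length_mm == 350.0
        assert path.legs == (path.legs[0],)
        assert path.legs[0].direction == "antegrade"

    def test_flow_direction_blocks_retrograde_travel(self, birth):
        a = QueryPoint.at("jejunum", 350.0)
        b = QueryPoint.at_landmark("ligament_of_treitz")
        assert path_distance(birth, a, b) is None
        assert path_distance(birth, a, b, undirected=True).total_length_mm == 350.0

    def test_point_on_resected_tissue_is_invalid(self, birth):
        post = apply_event(birth, _event("e1", "1990-01-01",
                                         _resect("ileum", 1000, 2000)))
        with pytest.raises(InvalidPointError):
            path_distance(post, QueryPoint.at("ileum", 1500.0),
                          QueryPoint.at_landmark("rectum_distal"))

    def test_query_point_by_link_id_resolves_to_endpoint(self, birth):
        post = apply_event(birth, _event(
            "e1", "1990-01-01", _resect("ileum", 1500, 1900),
            ReconstructionAnnotation("al1", "ileum", 1500.0, "ileum", 1900.0,
                                     "ileoileostomy", "luminal")))
        assert resolve_point(post, QueryPoint.at_link("al1"))[1] == 1900

    def test_distance_from_treitz_to_anastomosis(self, birth):
        # the kind of question the markup model answers in one query
        post = apply_event(birth, _event(
            "e1", "1990-01-01", _resect("ileum", 1500, 1900),
            ReconstructionAnnotation("al1", "ileum", 1500.0, "ileum", 1900.0,
                                     "ileoileostomy", "luminal")))
        path = path_distance(post, QueryPoint.at_landmark("ligament_of_treitz"),
                             QueryPoint.at_link("al1"))
        # 2000 mm jejunum + 1500 mm ileum + zero-length anastomosis
        assert path.total_length_mm == 3500.0
        assert "al1" in path.links_crossed

    def test_triangle_inequality(self, timeline_p2):
        state = timeline_p2.final_state
        pts = [QueryPoint.at_landmark("esophageal_inlet"),
               QueryPoint.at("jejunum", 800.0),
               QueryPoint.at_landmark("rectum_distal")]
        d = {}
        for i, a in enumerate(pts):
            for j, b in enumerate(pts):
                p = path_distance(state, a, b)
                if p is not None:
                    d[i, j] = p.total_length_mm
        for (i, j), dij in d.items():
            for k in range(len(pts)):
                if (i, k) in d and (k, j) in d:
                    assert dij <= d[i, k] + d[k, j] + 1e-9

    def test_resection_monotonicity(self, birth):
        # a resection without reconstruction never shortens a path and never
        # turns unreachable into reachable (anastomoses may shorten paths)
        cut = apply_event(birth, _event("e1", "1990-01-01",
                                        _resect("ileum", 1500, 1900)))
        treitz = QueryPoint.at_landmark("ligament_of_treitz")
        pairs = [(treitz, QueryPoint.at("ileum", 1000.0)),
                 (treitz, QueryPoint.at("ileum", 2500.0)),
                 (QueryPoint.at("ileum", 2000.0),
                  QueryPoint.at_landmark("rectum_distal"))]
        for a, b in pairs:
            before = path_distance(birth, a, b)
            after = path_distance(cut, a, b)
            if after is not None:
                assert before is not None
                assert after.total_length_mm >= before.total_length_mm


class TestContinuity:
    def test_birth_gut_is_continuous_end_to_end(self, birth):
        ok, witness = continuity_check(
            birth, QueryPoint.at_landmark("esophageal_inlet"),
            QueryPoint.at_landmark("rectum_distal"))
        assert ok and witness is not None
        assert witness.total_length_mm > 0

    def test_unbridged_resection_cuts_continuity(self, birth):
        post = apply_event(birth, _event("e1", "1990-01-01",
                                         _resect("jejunum", 500, 900)))
        ok, witness = continuity_check(
            post, QueryPoint.at_landmark("esophageal_inlet"),
            QueryPoint.at_landmark("rectum_distal"))
        assert not ok and witness is None

    def test_anastomosis_restores_continuity(self, birth):
        cut = apply_event(birth, _event("e1", "1990-01-01",
                                        _resect("jejunum", 500, 900)))
        bridged = apply_event(cut, _event("e2", "1991-01-01",
                                          ReconstructionAnnotation(
                                              "al1", "jejunum", 500.0,
                                              "jejunum", 900.0, "anastomosis",
                                              "luminal")))
        a = QueryPoint.at_landmark("esophageal_inlet")
        b = QueryPoint.at_landmark("rectum_distal")
        ok_before, _ = continuity_check(cut, a, b)
        ok_after, witness = continuity_check(bridged, a, b)
        assert (ok_before, ok_after) == (False, True)
        assert "al1" in witness.links_crossed


class TestSupplyingVessels:
    def test_direct_link_from_isolated_artery(self):
        ba = BasicAnatomy(
            (OrganClass("Arterial"), OrganClass("Intestine")),
            {s.id: s for s in (
                AnatomicalStructure("a1", "Artery", "Arterial", None, 0, 100, 3),
                AnatomicalStructure("gut", "Gut", "Intestine", None, 0, 500, 20))},
            (NaturalLink("a1", 100.0, "gut", 250.0, "arterial"),),
            {},
        )
        state = birth_state(ba, "tiny", dt.date(1960, 1, 1))
        assert supplying_vessels(state, "gut") == ["a1"]

    def test_whole_resection_of_vessel_removes_it(self, birth):
        post = apply_event(birth, _event(
            "e1", "1990-01-01", _resect("superior_mesenteric_artery")))
        assert supplying_vessels(post, "ileum") == []

    def test_branched_tree_matches_cell_graph_oracle(self, ba, birth, timeline_p2):
        for state in (birth, timeline_p2.final_state):
            for sid in ("ileum", "stomach", "pancreas", "liver",
                        "transverse_colon"):
                assert supplying_vessels(state, sid) == \
                    oracle_mm.oracle_supplying_vessels(state, sid)


class TestOracleEquivalence:
    """Segment-graph queries vs the explicit 1-mm cell graph."""

    POINTS = [("esophagus", 0), ("jejunum", 350), ("ileum", 2500),
              ("rectum", 150), ("pancreas", 50)]

    def _check_state(self, state):
        for i, (sa, oa) in enumerate(self.POINTS):
            for sb, ob in self.POINTS[i:]:
                reach_o, dist_o = oracle_mm.oracle_distance(
                    state, (sa, oa), (sb, ob), "luminal")
                try:
                    path = path_distance(state, QueryPoint.at(sa, float(oa)),
                                         QueryPoint.at(sb, float(ob)), "luminal")
                except InvalidPointError:
                    continue  # point off residual tissue: oracle node absent too
                assert (path is not None) == reach_o
                if path is not None:
                    assert abs(path.total_length_mm - dist_o) <= 1.0

    def test_fixture_states(self, timeline_p1, timeline_p2):
        for tl in (timeline_p1, timeline_p2):
            self._check_state(tl.birth_state)
            for _, state in tl.entries:
                self._check_state(state)

    def test_random_states(self, ba):
        for record in random_cases(ba, 8, seed0=500):
            self._check_state(compute_timeline(ba, record).final_state)
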