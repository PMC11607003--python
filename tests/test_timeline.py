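import copy
import datetime as dt
from dataclasses import replace
from fractions import Fraction
from functools import reduce

import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_cases
from sdmm.markup import (
    BiometricAnnotation,
    PatientRecord,
    ReconstructionAnnotation,
    ResectionAnnotation,
    SurgeryEvent,
    SurgicalStep,
    extract_deltas,
)
from sdmm.timeline_engine import (
    BeforeBirthError,
    DanglingAnastomosisError,
    ResectionConflictError,
    apply_event,
    birth_state,
    check_conservation,
    compute_timeline,
    reconstruct_from_deltas,
    state_at,
    surgical_load,
    _merge,
    _subtract,
    _width,
)


def _event(eid, date, *annots, title="Op"):
    return SurgeryEvent(eid, dt.date.fromisoformat(date), title,
                        (SurgicalStep(1, "", tuple(annots)),))


def _resect(sid, start=None, end=None):
    if start is None:
        return ResectionAnnotation(sid, "whole")
    return ResectionAnnotation(sid, "interval", float(start), float(end))


@pytest.fixture
def birth(ba):
    return birth_state(ba, "digestive-ba-v1", dt.date(1960, 1, 1))


class TestApplyEvent:
    def test_adhesiolysis_changes_nothing_but_the_date(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01"))
        assert replace(post, as_of_date=birth.as_of_date) == birth
        assert post.as_of_date == dt.date(1990, 5, 1)

    def test_whole_resection_empties_residual(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01", _resect("gallbladder")))
        assert post.residual_intervals("gallbladder") == ()
        assert post.residual_width("gallbladder") == 0
        assert "gallbladder" in post.removed_whole

    def test_overlapping_reresection_is_a_conflict(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01",
                                         _resect("ileum", 100, 200)))
        with pytest.raises(ResectionConflictError, match="ileum"):
            apply_event(post, _event("e2", "1991-05-01",
                                     _resect("ileum", 150, 250)))

    def test_clip_overlaps_intersects_with_residual(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01",
                                         _resect("ileum", 100, 200)))
        clipped = apply_event(post, _event("e2", "1991-05-01",
                                           _resect("ileum", 150, 250)),
                              clip_overlaps=True)
        assert clipped.residual_intervals("ileum") == (
            (Fraction(0), Fraction(100)), (Fraction(250), Fraction(3000)))
        # 100 mm from the first resection plus the clipped 50 mm overlap
        assert clipped.resected_length("ileum") == 150

    def test_input_state_never_mutated(self, birth):
        snapshot = copy.deepcopy(birth)
        apply_event(birth, _event("e1", "1990-05-01",
                                  _resect("jejunum", 0, 500),
                                  BiometricAnnotation("stomach", "diameter_mm", 55.0)))
        assert birth == snapshot

    def test_event_is_atomic_on_error(self, birth):
        bad = _event("e1", "1990-05-01",
                     _resect("jejunum", 0, 500),
                     _resect("jejunum", 400, 600))  # second one conflicts
        with pytest.raises(ResectionConflictError):
            apply_event(birth, bad)
        # nothing from the first annotation leaked anywhere
        assert birth.residual == {}

    def test_anastomosis_onto_resected_tissue_is_dangling(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01",
                                         _resect("ileum", 1000, 2000)))
        with pytest.raises(DanglingAnastomosisError):
            apply_event(post, _event("e2", "1991-05-01", ReconstructionAnnotation(
                "al1", "jejunum", 2000.0, "ileum", 1500.0, "anastomosis",
                "luminal")))

    def test_resection_stranding_an_anastomosis_is_refused(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01",
                                         _resect("ileum", 1500, 1900),
                                         ReconstructionAnnotation(
                                             "al1", "ileum", 1500.0, "ileum",
                                             1900.0, "ileoileostomy", "luminal")))
        with pytest.raises(DanglingAnastomosisError, match="al1"):
            apply_event(post, _event("e2", "1991-05-01",
                                     _resect("ileum", 1400, 1600)),
                        clip_overlaps=True)

    def test_detached_children_are_reported_not_removed(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01", _resect("cecum")))
        assert {"appendix", "ascending_colon"} <= post.detached
        # the ascending colon keeps its tissue; only its origination is gone
        assert post.residual_width("ascending_colon") == 150

    def test_length_override_rescales_prior_resections_proportionally(self, birth):
        post = apply_event(birth, _event("e1", "1990-05-01",
                                         _resect("jejunum", 0, 500)))
        scaled = apply_event(post, _event("e2", "1991-05-01",
                                          BiometricAnnotation("jejunum",
                                                              "length_mm", 1000.0)))
        assert scaled.residual_intervals("jejunum") == (
            (Fraction(250), Fraction(1000)),)
        assert scaled.resected_length("jejunum") == 250
        assert check_conservation(scaled) == 0


class TestComputeTimeline:
    def test_p1_yields_five_post_states(self, timeline_p1):
        assert len(timeline_p1.entries) == 5

    def test_birth_state_is_unmodified_ba(self, timeline_p1):
        s = timeline_p1.birth_state
        assert s.residual == {} and s.links == () and s.overrides == {}
        assert check_conservation(s) == 0

    def test_empty_record_gives_birth_only(self, ba):
        record = PatientRecord("T", dt.date(1960, 1, 1), "digestive-ba-v1")
        tl = compute_timeline(ba, record)
        assert tl.entries == () and tl.final_state == tl.birth_state

    def test_final_state_equals_independent_left_fold(self, ba, p2):
        tl = compute_timeline(ba, p2)
        events = sorted(p2.events, key=lambda e: (e.date, e.event_id))
        folded = reduce(apply_event,
                        events, birth_state(ba, p2.ba_reference, p2.birth_date))
        assert folded == tl.final_state

    def test_conflict_error_carries_event_context(self, ba):
        record = PatientRecord("T", dt.date(1960, 1, 1), "digestive-ba-v1", (
            _event("e1", "1990-01-01", _resect("ileum", 0, 100)),
            _event("e2", "1991-01-01", _resect("ileum", 50, 150),
                   title="Second look"),
        ))
        with pytest.raises(ResectionConflictError, match="e2"):
            compute_timeline(ba, record)


class TestStateAt:
    def test_date_before_first_surgery_is_birth_state(self, timeline_p1):
        assert state_at(timeline_p1, dt.date(1980, 1, 1)) == timeline_p1.birth_state

    def test_date_on_event_day_includes_that_event(self, timeline_p1, p1):
        e4 = p1.events[3]
        assert state_at(timeline_p1, e4.date) == timeline_p1.entries[3][1]

    def test_date_before_birth_raises(self, timeline_p1):
        with pytest.raises(BeforeBirthError):
            state_at(timeline_p1, dt.date(1940, 1, 1))

    def test_agrees_with_linear_scan(self, ba, timeline_p2):
        dates = [dt.date(y, m, 15) for y in range(1961, 2025, 3)
                 for m in (1, 7)]
        for d in dates:
            expected = timeline_p2.birth_state
            for event, post in timeline_p2.entries:
                if event.date <= d:
                    expected = post
            assert state_at(timeline_p2, d) == expected


class TestSurgicalLoad:
    def test_birth_entry_is_all_zeros(self, timeline_p2):
        entry = surgical_load(timeline_p2)[0]
        assert entry.total_surgeries == 0
        for load in entry.per_class.values():
            assert (load.resected_length_mm, load.whole_structures_removed,
                    load.artificial_links) == (0.0, 0, 0)

    def test_single_interval_resection_width(self, ba, birth):
        record = PatientRecord("T", dt.date(1960, 1, 1), "digestive-ba-v1",
                               (_event("e1", "1990-01-01",
                                       _resect("ileum", 100, 200)),))
        loads = surgical_load(compute_timeline(ba, record))
        assert loads[1].per_class["Intestine"].resected_length_mm == 100.0

    def test_p2_final_link_count_matches_annotation_recount(self, p2, timeline_p2):
        recount = sum(isinstance(a, ReconstructionAnnotation)
                      for e in p2.events for a in e.annotations)
        final = surgical_load(timeline_p2)[-1]
        assert sum(l.artificial_links for l in final.per_class.values()) == recount

    @pytest.mark.parametrize("case_idx", range(10))
    def test_load_is_nondecreasing_along_timeline(self, ba, timeline_p1,
                                                  timeline_p2, case_idx):
        records = list(random_cases(ba, 10, seed0=300))
        tl = compute_timeline(ba, records[case_idx])
        for timeline in (timeline_p1, timeline_p2, tl):
            loads = surgical_load(timeline)
            for prev, cur in zip(loads, loads[1:]):
                for cname, c in cur.per_class.items():
                    p = prev.per_class.get(cname)
                    prev_vals = ((p.resected_length_mm, p.whole_structures_removed,
                                  p.artificial_links) if p else (0.0, 0, 0))
                    assert prev_vals <= (c.resected_length_mm,
                                         c.whole_structures_removed,
                                         c.artificial_links)


class TestConservationAndDeltas:
    def test_conservation_exact_on_fixtures(self, timeline_p1, timeline_p2):
        for tl in (timeline_p1, timeline_p2):
            for _, state in [(None, tl.birth_state)] + list(tl.entries):
                assert check_conservation(state) == 0

    def test_conservation_exact_on_random_cases(self, ba):
        for record in random_cases(ba, 20, seed0=100):
            tl = compute_timeline(ba, record)
            for _, state in tl.entries:
                assert check_conservation(state) == 0

    def test_delta_reconstruction_equals_full_computation(self, ba, p1, p2):
        for record in [p1, p2] + list(random_cases(ba, 20, seed0=200)):
            tl = compute_timeline(ba, record)
            rebuilt = reconstruct_from_deltas(ba, extract_deltas(record),
                                              record.birth_date,
                                              record.ba_reference)
            assert rebuilt == tl.final_state

    def test_empty_deltas_give_birth_state(self, ba):
        state = reconstruct_from_deltas(ba, [], dt.date(1960, 1, 1),
                                        "digestive-ba-v1")
        assert state == birth_state(ba, "digestive-ba-v1", dt.date(1960, 1, 1))


# ---------------------------------------------------------------------------
# Interval arithmetic invariants

intervals_st = st.lists(
    st.tuples(st.integers(0, 100), st.integers(0, 100)).map(
        lambda t: (Fraction(min(t)), Fraction(max(t) + 1))),
    max_size=6,
)


class TestIntervalHelpers:
    @given(intervals_st)
    @settings(deadline=None, derandomize=True)
    def test_merge_is_sorted_disjoint_maximal_and_idempotent(self, ivs):
        merged = _merge(ivs)
        assert merged == _merge(merged)
        for (a, b), (c, d) in zip(merged, merged[1:]):
            assert a < b and c < d and b < c  # disjoint and maximal

    @given(intervals_st, intervals_st)
    @settings(deadline=None, derandomize=True)
    def test_subtract_conserves_width(self, ivs, cuts):
        base = _merge(ivs)
        cuts = _merge(cuts)
        remaining = _subtract(base, cuts)
        removed_width = sum(
            (min(b, d) - max(a, c)
             for a, b in base for c, d in cuts
             if min(b, d) > max(a, c)), Fraction(0))
        assert _width(remaining) + removed_width == _width(base)
        for a, b in remaining:
            assert not any(max(a, c) < min(b, d) for c, d in cuts)
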