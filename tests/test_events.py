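import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import quollscr as q
from quollscr.events import _make_survey
from quollscr.exceptions import ParameterError

from conftest import make_record


def _recs_at(minutes, station="c1", individual="q1"):
    base = pd.Timestamp("2020-07-01 12:00:00")
    return [
        make_record(station=station, individual=individual,
                    ts=base + pd.Timedelta(minutes=m))
        for m in minutes
    ]


class TestIndependenceFilter:
    def test_within_threshold_is_one_event(self):
        assert len(q.filter_independent_events(_recs_at([0, 5]))) == 1

    def test_strictly_over_threshold_splits(self):
        # 10 min 30 s > 10 min: two events
        assert len(q.filter_independent_events(_recs_at([0, 10.5]))) == 2

    def test_exactly_threshold_is_one_event(self):
        assert len(q.filter_independent_events(_recs_at([0, 10]))) == 1

    def test_simultaneous_at_two_stations_is_two_events(self):
        recs = _recs_at([0], station="c1") + _recs_at([0], station="c2")
        assert len(q.filter_independent_events(recs)) == 2

    def test_gap_measured_from_event_defining_record(self):
        # records at 0, 9, 18 min: the 9-min record is absorbed into the
        # first event, and 18 min is > 10 min from the event start
        events = q.filter_independent_events(_recs_at([0, 9, 18]))
        assert len(events) == 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            q.filter_independent_events(_recs_at([0]), threshold=pd.Timedelta(minutes=-1))

    def test_non_identifiable_records_rejected(self):
        bad = q.DetectionRecord("c1", None, pd.Timestamp("2020-07-01 20:00:00"),
                                "non_identifiable")
        with pytest.raises(ParameterError, match="non-identifiable"):
            q.filter_independent_events([bad])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(st.floats(min_value=0.1, max_value=60), min_size=1, max_size=25),
        thresholds=st.tuples(
            st.floats(min_value=0, max_value=30), st.floats(min_value=0, max_value=30)
        ),
    )
    def test_event_count_monotone_in_threshold(self, gaps, thresholds):
        lo, hi = sorted(thresholds)
        recs = _recs_at(np.cumsum(gaps))
        n_lo = len(q.filter_independent_events(recs, pd.Timedelta(minutes=lo)))
        n_hi = len(q.filter_independent_events(recs, pd.Timedelta(minutes=hi)))
        assert n_hi <= n_lo


class TestSurveySegmentation:
    dates = ["2020-07-01 10:00", "2020-09-01 09:00", "2020-11-01 11:00"]

    def _events(self, times):
        return [
            q.DetectionEvent("q1", "c1", pd.Timestamp(t)) for t in times
        ]

    def test_three_service_dates_give_two_surveys(self):
        surveys, assigned, un = q.segment_surveys(self._events([]), self.dates)
        assert len(surveys) == 2 and not un

    def test_event_at_service_datetime_joins_new_survey(self):
        surveys, assigned, _ = q.segment_surveys(
            self._events(["2020-09-01 09:00"]), self.dates
        )
        assert len(assigned[surveys[1].survey_id]) == 1
        assert not assigned[surveys[0].survey_id]

    def test_event_before_first_service_reported_unassigned(self):
        _, assigned, un = q.segment_surveys(
            self._events(["2020-06-30 23:00"]), self.dates
        )
        assert len(un) == 1 and not any(assigned.values())

    def test_non_increasing_dates_rejected(self):
        with pytest.raises(ParameterError):
            q.segment_surveys([], ["2020-07-01", "2020-07-01"])

    def test_partition_of_retained_events(self):
        times = ["2020-07-05 20:00", "2020-08-30 02:00", "2020-09-02 21:00",
                 "2020-10-31 23:30"]
        surveys, assigned, un = q.segment_surveys(self._events(times), self.dates)
        assert sum(len(v) for v in assigned.values()) + len(un) == len(times)
        assert not un


class TestTruncation:
    def test_sixty_nights_truncated_to_42(self):
        s = _make_survey("s", "2020-07-01 10:00", 60)
        trunc, _, _ = q.truncate_survey(s, 42)
        assert trunc.n_occasions == 42
        assert trunc.occasion_windows == s.occasion_windows[:42]

    def test_exactly_42_unchanged(self):
        s = _make_survey("s", "2020-07-01 10:00", 42)
        trunc, _, _ = q.truncate_survey(s, 42)
        assert trunc.occasion_windows == s.occasion_windows

    def test_short_survey_rejected_by_name(self):
        s = _make_survey("winter", "2020-07-01 10:00", 30)
        with pytest.raises(ParameterError, match="winter"):
            q.truncate_survey(s, 42)

    def test_late_events_dropped_and_counted(self):
        s = _make_survey("s", "2020-07-01 10:00", 60)
        evs = [
            q.DetectionEvent("q1", "c1", pd.Timestamp("2020-07-05 20:00")),
            q.DetectionEvent("q1", "c1", pd.Timestamp("2020-08-25 20:00")),  # night 55
        ]
        trunc, kept, dropped = q.truncate_survey(s, 42, events=evs)
        assert len(kept) == 1 and dropped == 1


class TestBuildCapthist:
    def _survey(self):
        return _make_survey("s", "2020-07-01 10:00", 42)

    def test_repeat_events_collapse_to_single_entry(self, pair_detectors):
        s = self._survey()
        t0 = pd.Timestamp("2020-07-01 20:00")
        evs = [
            q.DetectionEvent("q1", "a", t0 + pd.Timedelta(minutes=20 * j))
            for j in range(3)
        ]
        ch = q.build_capthist(evs, s, pair_detectors)
        assert ch.incidence.sum() == 1
        assert ch.incidence[0, 0, 0] == 1

    def test_morning_event_belongs_to_previous_noon_occasion(self, pair_detectors):
        s = self._survey()
        ev = q.DetectionEvent("q1", "a", pd.Timestamp("2020-07-03 11:59:00"))
        ch = q.build_capthist([ev], s, pair_detectors)
        assert s.occasion_of(ev.timestamp) == 2
        assert ch.incidence[0, 1, 0] == 1

    def test_event_outside_windows_rejected(self, pair_detectors):
        s = self._survey()
        ev = q.DetectionEvent("q1", "a", pd.Timestamp("2021-07-01 20:00"))
        with pytest.raises(ParameterError, match="outside"):
            q.build_capthist([ev], s, pair_detectors)

    def test_non_chosen_side_individuals_excluded(self, pair_detectors):
        s = self._survey()
        t0 = pd.Timestamp("2020-07-01 20:00")
        evs = [
            q.DetectionEvent("qc", "a", t0),
            q.DetectionEvent("ql", "a", t0),
            q.DetectionEvent("qr", "b", t0),
        ]
        profiles = {"qc": "complete", "ql": "semi_left", "qr": "semi_right"}
        ch = q.build_capthist(evs, s, pair_detectors, profiles=profiles,
                              chosen_side="left")
        assert ch.individuals == ("qc", "ql")

    def test_entry_count_never_exceeds_event_count(self, grid25):
        cfg = q.SimulationConfig(seed=21)
        records, detectors, gen_events, _ = q.simulate_raw_records(cfg)
        survey = q.simulation_survey(cfg)
        ch = q.build_capthist(gen_events, survey, detectors)
        assert ch.n_individuals == len({e.individual_id for e in gen_events})
        assert ch.incidence.sum() <= len(gen_events)
        # equality iff no two events share (individual, occasion, detector)
        cells = {
            (e.individual_id, survey.occasion_of(e.timestamp), e.station_id)
            for e in gen_events
        }
        assert ch.incidence.sum() == len(cells)
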