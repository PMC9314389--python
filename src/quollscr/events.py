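"""From identified records to independent events and detection histories.

A camera visit produces many image sequences; repeat sequences of one
individual at one camera are collapsed to *independent detection events*
separated by more than a threshold gap (10 min by default).  Surveys are
segmented at camera-service dates, standardised to their first 42 nights,
and events are binned into noon-to-noon occasions to give the binary
individuals x occasions x detectors history the SCR likelihood consumes.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import CaptHist, DetectionEvent, DetectionRecord, DetectorArray, Survey
from .exceptions import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_INDEPENDENCE_MINUTES = 10.0
DEFAULT_SURVEY_NIGHTS = 42


def filter_independent_events(
    records: Iterable[DetectionRecord],
    threshold: pd.Timedelta = pd.Timedelta(minutes=DEFAULT_INDEPENDENCE_MINUTES),
) -> List[DetectionEvent]:
    """Collapse identified records into independent detection events.

    Within each (individual, station) stream, in time order, a record
    starts a new event iff its gap from the previous *retained* event is
    strictly greater than ``threshold``.  Records at different stations are
    always separate events; non-identifiable records must have been
    excluded upstream (identity is required for capture-recapture).
    """
    threshold = pd.Timedelta(threshold)
    if threshold < pd.Timedelta(0):
        raise ParameterError(f"independence threshold must be >= 0, got {threshold}")
    streams: Dict[Tuple[str, str], List[DetectionRecord]] = {}
    for r in records:
        if r.individual_id is None:
            raise ParameterError(
                "non-identifiable records cannot form detection events; "
                "exclude them before the independence filter"
            )
        streams.setdefault((r.individual_id, r.station_id), []).append(r)
    events: List[DetectionEvent] = []
    for (indiv, station), recs in streams.items():
        recs.sort(key=lambda r: r.timestamp)
        last_event_time = None
        for r in recs:
            if last_event_time is None or (r.timestamp - last_event_time) > threshold:
                events.append(
                    DetectionEvent(
                        individual_id=indiv,
                        station_id=station,
                        timestamp=r.timestamp,
                    )
                )
                last_event_time = r.timestamp
    events.sort(key=lambda e: (e.individual_id, e.station_id, e.timestamp))
    return events


def _make_survey(
    survey_id: str, start: pd.Timestamp, n_nights: int, source_study: str = ""
) -> Survey:
    """Build a survey of ``n_nights`` noon-to-noon occasions from ``start``.

    The first occasion begins at the first 12:00:00 at or after the survey
    start (the service visit); any partial first day before that noon is
    outside the survey.
    """
    start = pd.Timestamp(start)
    noon = start.normalize() + pd.Timedelta(hours=12)
    if noon < start:
        noon += pd.Timedelta(days=1)
    windows = tuple(
        (noon + pd.Timedelta(days=t), noon + pd.Timedelta(days=t + 1))
        for t in range(n_nights)
    )
    return Survey(
        survey_id=survey_id, start=start, occasion_windows=windows,
        source_study=source_study,
    )


def segment_surveys(
    events: Sequence[DetectionEvent],
    service_dates: Sequence,
    source_study: str = "",
    survey_prefix: str = "S",
) -> Tuple[List[Survey], Dict[str, List[DetectionEvent]], List[DetectionEvent]]:
    """Split events into surveys delimited by camera-service dates.

    ``k`` service dates delimit ``k - 1`` surveys; each survey's interval
    is closed at its service datetime and open at the next, so an event
    exactly at a service time belongs to the new survey.  Surveys here are
    *untruncated*: their occasion windows run from the first noon at or
    after the service date up to the next service date, and are cut to 42
    nights by :func:`truncate_survey`.

    Returns (surveys, events per survey_id, unassigned events).  Events
    before the first service date or at/after the last are unassigned and
    reported via logging.
    """
    dates = [pd.Timestamp(d) for d in service_dates]
    if any(b <= a for a, b in zip(dates[:-1], dates[1:])):
        raise ParameterError("service_dates must be strictly increasing")
    if len(dates) < 2:
        raise ParameterError("need >= 2 service dates to delimit a survey")
    surveys: List[Survey] = []
    for i, (a, b) in enumerate(zip(dates[:-1], dates[1:]), start=1):
        noon = a.normalize() + pd.Timedelta(hours=12)
        if noon < a:
            noon += pd.Timedelta(days=1)
        n_nights = int((b - noon) // pd.Timedelta(days=1))
        if n_nights < 1:
            raise ParameterError(
                f"service interval {a} .. {b} too short for one full occasion"
            )
        sid = f"{survey_prefix}{i:02d}"
        surveys.append(_make_survey(sid, a, n_nights, source_study=source_study))

    assigned: Dict[str, List[DetectionEvent]] = {s.survey_id: [] for s in surveys}
    unassigned: List[DetectionEvent] = []
    for ev in events:
        t = ev.timestamp
        placed = False
        for s, (a, b) in zip(surveys, zip(dates[:-1], dates[1:])):
            if a <= t < b:
                assigned[s.survey_id].append(
                    DetectionEvent(ev.individual_id, ev.station_id, t, s.survey_id)
                )
                placed = True
                break
        if not placed:
            unassigned.append(ev)
    if unassigned:
        logger.warning(
            "%d event(s) fall outside all service intervals and were not "
            "assigned to any survey", len(unassigned),
        )
    return surveys, assigned, unassigned


def truncate_survey(
    survey: Survey, n_nights: int = DEFAULT_SURVEY_NIGHTS,
    events: Optional[Sequence[DetectionEvent]] = None,
) -> Tuple[Survey, List[DetectionEvent], int]:
    """Standardise a survey to its first ``n_nights`` occasions.

    Surveys of unequal length are not comparable (more nights mean more
    detections), so every survey is cut back to the duration of the
    shortest.  Returns the truncated survey, the retained events, and the
    number of events dropped (also logged).

    Raises
    ------
    ParameterError
        If the survey has fewer than ``n_nights`` occasions.
    """
    if survey.n_occasions < n_nights:
        raise ParameterError(
            f"survey {survey.survey_id!r} has only {survey.n_occasions} "
            f"night(s); cannot truncate to {n_nights}"
        )
    trunc = Survey(
        survey_id=survey.survey_id,
        start=survey.start,
        occasion_windows=survey.occasion_windows[:n_nights],
        source_study=survey.source_study,
    )
    kept: List[DetectionEvent] = []
    dropped = 0
    if events is not None:
        for ev in events:
            if trunc.occasion_of(ev.timestamp) is not None:
                kept.append(ev)
            else:
                dropped += 1
        if dropped:
            logger.info(
                "survey %s: dropped %d event(s) after night %d",
                survey.survey_id, dropped, n_nights,
            )
    return trunc, kept, dropped


def build_capthist(
    events: Sequence[DetectionEvent],
    survey: Survey,
    detectors: DetectorArray,
    profiles: Optional[dict] = None,
    chosen_side: Optional[str] = None,
) -> CaptHist:
    """Bin events into a binary spatial detection history.

    ``incidence[i, t, k] = 1`` iff individual ``i`` had at least one
    independent event at detector ``k`` during occasion ``t`` (proximity
    collapse).  If ``profiles`` (individual -> profile_class) and
    ``chosen_side`` are given, individuals whose profile is the non-chosen
    semi side are excluded.  Individuals are ordered alphabetically.

    Raises
    ------
    ParameterError
        If any event timestamp falls outside the survey's occasion windows
        (such events should have been truncated away upstream).
    """
    excluded_class = None
    if chosen_side is not None:
        excluded_class = "semi_right" if chosen_side == "left" else "semi_left"
    use: List[DetectionEvent] = []
    for ev in events:
        if (
            excluded_class is not None
            and profiles is not None
            and profiles.get(ev.individual_id) == excluded_class
        ):
            continue
        use.append(ev)
    individuals = sorted({ev.individual_id for ev in use})
    idx = {a: i for i, a in enumerate(individuals)}
    inc = np.zeros((len(individuals), survey.n_occasions, detectors.n), dtype=np.uint8)
    for ev in use:
        occ = survey.occasion_of(ev.timestamp)
        if occ is None:
            raise ParameterError(
                f"event at {ev.timestamp} lies outside survey "
                f"{survey.survey_id!r} occasion windows"
            )
        inc[idx[ev.individual_id], occ - 1, detectors.index(ev.station_id)] = 1
    return CaptHist(individuals, detectors.station_ids, inc, survey_id=survey.survey_id)
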