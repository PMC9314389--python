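import numpy as np
import pandas as pd
import pytest

import quollscr as q

# Published per-survey density estimates (animals per km^2) from the quoll
# camera-trap study this package re-implements: 12 surveys at the
# fragmented site, 7 at the intact site.  Used as inputs to the
# cross-survey summary computations.
FRAGMENTED_DENSITIES = (
    0.23, 0.21, 0.51, 0.33, 0.42, 0.29, 0.18,  # study 1
    0.24, 0.35,                                  # study 2
    0.27, 0.13, 0.66,                            # study 3
)
INTACT_DENSITIES = (0.40, 0.47, 0.37, 0.35, 0.28, 0.48, 0.35)

# Published sequence-assignment counts (complete / semi / non-identifiable)
ASSIGNMENT_COUNTS = {
    "fragmented_study1": (2112, 13, 71),
    "fragmented_study2": (418, 0, 22),
    "fragmented_study3": (1241, 13, 40),
    "intact": (3098, 43, 144),
}


@pytest.fixture(scope="session")
def grid25():
    """5 x 5 camera grid at 500 m spacing (the package's default design)."""
    return q.grid_detectors()


@pytest.fixture
def pair_detectors():
    return q.DetectorArray(["a", "b"], [(0.0, 0.0), (300.0, 0.0)])


@pytest.fixture
def tiny_mask(pair_detectors):
    return q.build_mask(pair_detectors, buffer=400.0, spacing=300.0)


def make_record(station="c1", individual="q1", ts="2020-07-01 20:00:00",
                profile="complete", n_images=10):
    return q.DetectionRecord(
        station_id=station, individual_id=individual,
        timestamp=pd.Timestamp(ts), profile_class=profile, n_images=n_images,
    )


def make_nonid(station="c1", ts="2020-07-01 20:00:00"):
    return q.DetectionRecord(
        station_id=station, individual_id=None, timestamp=pd.Timestamp(ts),
        profile_class="non_identifiable",
    )


def records_with_counts(n_complete, n_semi, n_nonid, semi_left=None):
    """Build a synthetic record list with given assignment-class counts."""
    if semi_left is None:
        semi_left = n_semi
    recs = []
    t0 = pd.Timestamp("2020-07-01 18:00:00")
    step = pd.Timedelta(minutes=15)
    i = 0
    for j in range(n_complete):
        recs.append(make_record(individual=f"c{j}", ts=t0 + i * step)); i += 1
    for j in range(n_semi):
        side = "semi_left" if j < semi_left else "semi_right"
        recs.append(make_record(individual=f"s{j}", ts=t0 + i * step,
                                profile=side)); i += 1
    for j in range(n_nonid):
        recs.append(make_nonid(ts=t0 + i * step)); i += 1
    return recs


@pytest.fixture
def events_18_quolls():
    """Synthetic survey matching a published survey row: 18 individuals,
    73 independent events, 15 re-detected, 11 at >= 2 stations."""
    survey = q.simulation_survey(q.SimulationConfig(seed=0))
    base = survey.occasion_windows[0][0] + pd.Timedelta(hours=9)
    events = []

    def add(ind, station, n, start_occ=0):
        for j in range(n):
            t = base + pd.Timedelta(days=(start_occ + j) % 42, minutes=30 * j)
            events.append(q.DetectionEvent(ind, station, t, survey.survey_id))

    for j in range(3):                      # seen once only
        add(f"q{j:02d}", "C01", 1, start_occ=j)
    for j in range(3, 14):                  # re-detected at 2 stations
        add(f"q{j:02d}", "C01", 2, start_occ=j)
        add(f"q{j:02d}", "C02", 2, start_occ=j + 1)
    extra = [6, 6, 7, 7]
    for j, n in zip(range(14, 18), extra):  # re-detected, single station
        add(f"q{j:02d}", "C03", n, start_occ=j % 10)
    assert len(events) == 3 + 11 * 4 + sum(extra) == 73
    return survey, events
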