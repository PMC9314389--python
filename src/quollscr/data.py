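"""Core domain containers shared across the pipeline.

The analysis moves through three representations of the same field data:
timestamped image-sequence records (``DetectionRecord``), independent
detection events (``DetectionEvent``), and per-survey spatial detection
histories (``CaptHist``: individuals x occasions x detectors binary
incidence).  Camera locations are held in a ``DetectorArray`` with planar
metre coordinates, as spatial capture-recapture distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError

#: Recognised photo-identification profile classes.  A profile is
#: "complete" when both lateral sides of the animal are catalogued,
#: "semi_left"/"semi_right" when only one side is, and "non_identifiable"
#: when the sequence could not be matched to any profile.
PROFILE_CLASSES = ("complete", "semi_left", "semi_right", "non_identifiable")


@dataclass(frozen=True)
class DetectionRecord:
    """One identified, timestamped camera-trigger image sequence.

    Parameters
    ----------
    station_id : str
        Camera station at which the sequence was recorded.
    individual_id : str or None
        Catalogue tag of the animal; ``None`` exactly when the sequence is
        non-identifiable.
    timestamp : pandas.Timestamp
        Trigger time of the first image in the sequence (wall-clock local
        time; field data carry 1-second resolution).
    profile_class : str
        One of :data:`PROFILE_CLASSES`.
    n_images : int
        Number of images in the rapid-fire sequence (10 per trigger for
        the cameras emulated here; >= 1).
    """

    station_id: str
    individual_id: Optional[str]
    timestamp: pd.Timestamp
    profile_class: str
    n_images: int = 10

    def __post_init__(self):
        if self.profile_class not in PROFILE_CLASSES:
            raise ParameterError(
                f"unknown profile_class {self.profile_class!r}; "
                f"expected one of {PROFILE_CLASSES}"
            )
        if (self.individual_id is None) != (self.profile_class == "non_identifiable"):
            raise ParameterError(
                "individual_id must be None exactly when the sequence is "
                f"non_identifiable (got id={self.individual_id!r}, "
                f"class={self.profile_class!r})"
            )
        if self.n_images < 1:
            raise ParameterError(f"n_images must be >= 1, got {self.n_images}")
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))


@dataclass(frozen=True)
class DetectionEvent:
    """One independent detection of an individual at a station."""

    individual_id: str
    station_id: str
    timestamp: pd.Timestamp
    survey_id: Optional[str] = None


class DetectorArray:
    """Camera-trap locations in a planar metre coordinate system.

    Parameters
    ----------
    station_ids : sequence of str
        Unique station labels, in array order.
    xy : array-like, shape (K, 2)
        Easting/northing coordinates in metres.
    usage : array-like of {0, 1}, shape (K, n_occasions), optional
        Per-station per-occasion activity indicator; ``None`` means every
        station was active on every occasion.
    """

    def __init__(self, station_ids: Sequence[str], xy, usage=None):
        ids = [str(s) for s in station_ids]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise SchemaError(f"duplicate station_id(s): {dupes}")
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape != (len(ids), 2):
            raise SchemaError(
                f"xy must have shape ({len(ids)}, 2), got {xy.shape}"
            )
        if not np.all(np.isfinite(xy)):
            raise SchemaError("detector coordinates must be finite")
        if usage is not None:
            usage = np.asarray(usage)
            if usage.shape[0] != len(ids):
                raise SchemaError(
                    "usage must have one row per station "
                    f"({len(ids)}), got {usage.shape}"
                )
            if not np.isin(usage, (0, 1)).all():
                raise SchemaError("usage entries must be 0 or 1")
            usage = usage.astype(np.uint8)
        self.station_ids = tuple(ids)
        self.xy = xy
        self.usage = usage
        self._index = {s: i for i, s in enumerate(ids)}

    @property
    def n(self) -> int:
        return len(self.station_ids)

    def index(self, station_id: str) -> int:
        return self._index[station_id]

    def __contains__(self, station_id: str) -> bool:
        return station_id in self._index

    def bounding_box(self):
        """(xmin, ymin, xmax, ymax) of the array."""
        return (*self.xy.min(axis=0), *self.xy.max(axis=0))

    def nearest_neighbour_distances(self) -> np.ndarray:
        """Distance from each station to its closest neighbour (metres)."""
        if self.n == 1:
            return np.array([np.inf])
        d = np.hypot(
            self.xy[:, None, 0] - self.xy[None, :, 0],
            self.xy[:, None, 1] - self.xy[None, :, 1],
        )
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"station_id": self.station_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]}
        )

    def __repr__(self):
        return f"DetectorArray(n={self.n})"


class CaptHist:
    """Binary spatial detection history for one survey.

    ``incidence[i, t, k]`` is 1 when individual ``i`` was detected at
    detector ``k`` at least once during occasion ``t`` (a proximity
    detector collapses repeat visits within an occasion to presence).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        detector_ids: Sequence[str],
        incidence,
        survey_id: Optional[str] = None,
    ):
        incidence = np.asarray(incidence)
        if incidence.ndim != 3:
            raise ParameterError(
                f"incidence must be 3-d (individuals, occasions, detectors), "
                f"got shape {incidence.shape}"
            )
        if not np.isin(incidence, (0, 1)).all():
            raise ParameterError("incidence must be binary")
        n, _, k = incidence.shape
        if n != len(individuals):
            raise ParameterError("incidence first axis must match individuals")
        if k != len(detector_ids):
            raise ParameterError("incidence last axis must match detector_ids")
        if n and not incidence.reshape(n, -1).any(axis=1).all():
            raise ParameterError("every individual must have >= 1 detection")
        self.individuals = tuple(str(i) for i in individuals)
        self.detector_ids = tuple(str(s) for s in detector_ids)
        self.incidence = incidence.astype(np.uint8)
        self.survey_id = survey_id

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return self.incidence.shape[1]

    @property
    def n_detectors(self) -> int:
        return len(self.detector_ids)

    def detectors_per_individual(self) -> np.ndarray:
        """Number of distinct detectors at which each individual appears."""
        return self.incidence.any(axis=1).sum(axis=1)

    def n_spatial_redetections(self) -> int:
        """Count of individuals detected at two or more detectors."""
        if self.n_individuals == 0:
            return 0
        return int((self.detectors_per_individual() >= 2).sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per positive (individual, occasion, detector)."""
        idx = np.argwhere(self.incidence == 1)
        return pd.DataFrame(
            {
                "individual_id": [self.individuals[i] for i in idx[:, 0]],
                "occasion": idx[:, 1] + 1,
                "detector_id": [self.detector_ids[k] for k in idx[:, 2]],
            }
        )

    def __eq__(self, other):
        return (
            isinstance(other, CaptHist)
            and self.individuals == other.individuals
            and self.detector_ids == other.detector_ids
            and self.incidence.shape == other.incidence.shape
            and np.array_equal(self.incidence, other.incidence)
        )

    def __repr__(self):
        return (
            f"CaptHist(individuals={self.n_individuals}, "
            f"occasions={self.n_occasions}, detectors={self.n_detectors}, "
            f"detections={int(self.incidence.sum())})"
        )


@dataclass
class Survey:
    """A standardised survey period of contiguous noon-to-noon occasions.

    Each occasion window runs from 12:00:00 on one day to (but excluding)
    12:00:00 the next, so a nocturnal activity bout is never split across
    occasions.
    """

    survey_id: str
    start: pd.Timestamp
    occasion_windows: tuple  # of (Timestamp, Timestamp), half-open [start, end)
    source_study: str = ""

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        wins = tuple((pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.occasion_windows)
        for (a, b) in wins:
            if not a < b:
                raise ParameterError("occasion window start must precede end")
        for (_, b0), (a1, _) in zip(wins[:-1], wins[1:]):
            if b0 != a1:
                raise ParameterError("occasion windows must be contiguous")
        self.occasion_windows = wins

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_windows)

    @property
    def first_noon(self) -> pd.Timestamp:
        return self.occasion_windows[0][0]

    @property
    def end(self) -> pd.Timestamp:
        return self.occasion_windows[-1][1]

    def occasion_of(self, timestamp) -> Optional[int]:
        """1-based occasion index containing ``timestamp``, or None."""
        t = pd.Timestamp(timestamp)
        if not (self.first_noon <= t < self.end):
            return None
        return int((t - self.first_noon) // pd.Timedelta(days=1)) + 1


@dataclass
class ProfileCatalogue:
    """Photo-identification catalogue bookkeeping for one site.

    Tracks each profiled individual's class, per-class sequence counts and
    (once selected) which lateral side's semi-complete profiles are carried
    into the detection histories.
    """

    profiles: dict = field(default_factory=dict)  # individual_id -> profile_class
    sequence_counts: dict = field(default_factory=dict)  # profile_class -> n sequences
    site: str = ""
    chosen_side: Optional[str] = None

    @classmethod
    def from_records(cls, records: Iterable[DetectionRecord], site: str = "") -> "ProfileCatalogue":
        profiles: dict = {}
        counts = {c: 0 for c in PROFILE_CLASSES}
        for r in records:
            counts[r.profile_class] += 1
            if r.individual_id is not None:
                prev = profiles.setdefault(r.individual_id, r.profile_class)
                if prev != r.profile_class:
                    raise ParameterError(
                        f"individual {r.individual_id!r} appears with profile "
                        f"classes {prev!r} and {r.profile_class!r}"
                    )
        return cls(profiles=profiles, sequence_counts=counts, site=site)

    def side_counts(self) -> tuple[int, int]:
        """(n left-side-only profiles, n right-side-only profiles)."""
        vals = list(self.profiles.values())
        return vals.count("semi_left"), vals.count("semi_right")
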