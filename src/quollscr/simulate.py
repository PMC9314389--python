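"""Ground-truth-known synthetic camera-trap data.

Two levels of generation are provided.  ``simulate_capthist`` draws a
spatial Poisson population of activity centres and per-occasion
per-detector Bernoulli detections under the half-normal SCR model (with
any of the behavioural/time baseline-encounter effects), returning a
detection history plus the latent truth.  ``simulate_raw_records``
expands those detections into timestamped 10-image trigger sequences —
with retrigger bursts, an optional non-identifiable fraction and
single-side (semi) profiles — so the full identification/eventing
pipeline can be exercised against known generating events.

Defaults mirror the field design the package targets: 25 cameras on a
5 x 5 grid at 500 m spacing, 42 noon-to-noon occasions, density
0.4 animals per km^2, g0 = 0.08 and sigma = 500 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import CaptHist, DetectionEvent, DetectionRecord, DetectorArray, Survey
from .events import _make_survey
from .exceptions import ParameterError
from .records import write_detection_table, write_detector_layout


def grid_detectors(nx: int = 5, ny: int = 5, spacing: float = 500.0,
                   origin: Tuple[float, float] = (0.0, 0.0)) -> DetectorArray:
    """A regular nx x ny camera grid (default 5 x 5 at 500 m)."""
    ids, xy = [], []
    for j in range(ny):
        for i in range(nx):
            ids.append(f"C{j * nx + i + 1:02d}")
            xy.append((origin[0] + i * spacing, origin[1] + j * spacing))
    return DetectorArray(ids, xy)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the generator.

    seed is mandatory; all randomness flows through one
    ``numpy.random.Generator`` seeded with it (no global state).
    ``buffer_sim`` is the half-width (metres) by which the detector
    bounding box is expanded to form the rectangle holding activity
    centres; the default 4 sigma keeps animals with any appreciable
    detection probability inside the simulated region.
    """

    seed: int
    D: float = 0.4                      # animals per km^2
    g0: float = 0.08                    # baseline encounter probability
    sigma: float = 500.0                # metres
    beta1: float = 0.0                  # logit-scale response / trend effect
    response_code: str = "0"            # one of 0, b, bk, B, Bk, T
    detectors: DetectorArray = field(default_factory=grid_detectors)
    n_occasions: int = 42
    buffer_sim: Optional[float] = None  # default 4 * sigma
    survey_start: str = "2020-07-01 12:00:00"
    # raw-stream options
    images_per_trigger: int = 10
    mean_extra_triggers: float = 1.0    # triggers per event ~ 1 + Poisson
    mean_extra_events: float = 0.5      # events per positive cell ~ 1 + Poisson
    non_identifiable_fraction: float = 0.0
    semi_profile_fraction: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.D < 0:
            raise ParameterError("D must be >= 0")
        if not 0.0 < self.g0 < 1.0:
            raise ParameterError("g0 must lie in (0, 1)")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.response_code not in ("0", "b", "bk", "B", "Bk", "T"):
            raise ParameterError(f"unknown response_code {self.response_code!r}")
        for name in ("non_identifiable_fraction", "semi_profile_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.n_occasions < 1:
            raise ParameterError("n_occasions must be >= 1")
        if self.buffer_sim is None:
            self.buffer_sim = 4.0 * self.sigma

    @property
    def region(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the simulated rectangle."""
        xmin, ymin, xmax, ymax = self.detectors.bounding_box()
        b = self.buffer_sim
        return (xmin - b, ymin - b, xmax + b, ymax + b)

    @property
    def region_area_km2(self) -> float:
        xmin, ymin, xmax, ymax = self.region
        return (xmax - xmin) * (ymax - ymin) / 1e6


@dataclass
class GroundTruth:
    """Latent simulation state: all animals, detected or not."""

    ids: tuple            # all simulated animals
    centers: np.ndarray   # (N, 2) metres
    n_animals: int        # realised N ~ Poisson(D * area)
    detected: np.ndarray  # (N,) bool
    detections: np.ndarray  # (N, T, K) uint8, full incidence incl. undetected


def simulate_capthist(config: SimulationConfig) -> Tuple[CaptHist, GroundTruth]:
    """Draw one survey's detection history under the generating model.

    Centres are uniform on the buffered rectangle with
    N ~ Poisson(D * area); each animal/occasion/detector is an
    independent Bernoulli with
    ``p = invlogit(logit(g0) + beta1 * z) * exp(-d^2 / (2 sigma^2))``,
    where z follows ``response_code`` and is updated from the animal's own
    realised history (strictly previous occasions).  Animals never
    detected are excluded from the CaptHist but kept in the truth.
    """
    rng = np.random.default_rng(config.seed)
    xmin, ymin, xmax, ymax = config.region
    N = int(rng.poisson(config.D * config.region_area_km2))
    centers = np.column_stack(
        [rng.uniform(xmin, xmax, N), rng.uniform(ymin, ymax, N)]
    )
    T, K = config.n_occasions, config.detectors.n
    ids = tuple(f"A{i + 1:03d}" for i in range(N))
    Y = np.zeros((N, T, K), dtype=np.uint8)
    if N > 0:
        d = np.hypot(
            centers[:, 0][:, None] - config.detectors.xy[None, :, 0],
            centers[:, 1][:, None] - config.detectors.xy[None, :, 1],
        )
        h = np.exp(-(d ** 2) / (2.0 * config.sigma ** 2))  # (N, K)
        b0 = float(logit(config.g0))
        code, b1 = config.response_code, config.beta1
        t_idx = np.arange(1, T + 1, dtype=float)
        u = (t_idx - (T + 1) / 2.0) / T
        ever_any = np.zeros(N, dtype=bool)
        ever_at = np.zeros((N, K), dtype=bool)
        for t in range(T):
            if code == "0":
                g = expit(b0) * np.ones((N, K))
            elif code == "b":
                g = expit(b0 + b1 * ever_any)[:, None] * np.ones((1, K))
            elif code == "bk":
                g = expit(b0 + b1 * ever_at)
            elif code == "B":
                prev = Y[:, t - 1, :].any(axis=1) if t > 0 else np.zeros(N, bool)
                g = expit(b0 + b1 * prev)[:, None] * np.ones((1, K))
            elif code == "Bk":
                prev = Y[:, t - 1, :].astype(bool) if t > 0 else np.zeros((N, K), bool)
                g = expit(b0 + b1 * prev)
            else:  # T
                g = expit(b0 + b1 * u[t]) * np.ones((N, K))
            p = g * h
            Y[:, t, :] = rng.random((N, K)) < p
            ever_any |= Y[:, t, :].any(axis=1)
            ever_at |= Y[:, t, :].astype(bool)

    detected = Y.reshape(N, T * K).any(axis=1)
    truth = GroundTruth(
        ids=ids, centers=centers, n_animals=N, detected=detected, detections=Y
    )
    det_idx = np.nonzero(detected)[0]
    ch = CaptHist(
        [ids[i] for i in det_idx],
        config.detectors.station_ids,
        Y[det_idx],
        survey_id="SIM01",
    )
    return ch, truth


def simulation_survey(config: SimulationConfig) -> Survey:
    """The noon-to-noon occasion calendar of the simulated survey."""
    return _make_survey(
        "SIM01", pd.Timestamp(config.survey_start), config.n_occasions,
        source_study="simulation",
    )


def simulate_raw_records(
    config: SimulationConfig,
) -> Tuple[List[DetectionRecord], DetectorArray, List[DetectionEvent], GroundTruth]:
    """Expand a simulated history into raw timestamped trigger sequences.

    Each positive (animal, occasion, detector) cell produces one or more
    independent visits (events) during that night, spaced more than 10
    minutes apart so the independence filter reconstructs them; each
    visit produces 1 + Poisson(``mean_extra_triggers``) 10-image trigger
    sequences with gaps of 0.5 s (an immediate retrigger, merged by
    sequence linking) or 5-60 s (merged by the 10-min rule).  A fraction
    of sequences is relabelled non-identifiable, and a fraction of
    individuals carries a single-side (semi) profile instead of a
    complete one.

    Returns (records, detectors, generating events, ground truth).
    """
    ch, truth = simulate_capthist(config)
    # an independent generator stream for the raw expansion, so the
    # detection history itself matches simulate_capthist(config) exactly
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    survey = simulation_survey(config)

    profile_of = {}
    for ind in ch.individuals:
        if rng.random() < config.semi_profile_fraction:
            profile_of[ind] = "semi_left" if rng.random() < 0.5 else "semi_right"
        else:
            profile_of[ind] = "complete"

    records: List[DetectionRecord] = []
    gen_events: List[DetectionEvent] = []
    for i, ind in enumerate(ch.individuals):
        for t, k in np.argwhere(ch.incidence[i]):
            win_start, _ = survey.occasion_windows[t]
            n_events = 1 + int(min(rng.poisson(config.mean_extra_events), 3))
            # nocturnal visits: first between 20:00 and 02:00, later ones
            # 11-120 min apart; all comfortably inside the noon-noon window
            offset = rng.uniform(8.0, 14.0) * 3600.0
            for _e in range(n_events):
                event_time = win_start + pd.Timedelta(seconds=round(offset))
                gen_events.append(
                    DetectionEvent(
                        individual_id=ind,
                        station_id=ch.detector_ids[k],
                        timestamp=event_time,
                        survey_id=survey.survey_id,
                    )
                )
                n_triggers = 1 + int(min(rng.poisson(config.mean_extra_triggers), 4))
                seq_time = event_time
                for j in range(n_triggers):
                    if rng.random() < config.non_identifiable_fraction:
                        rec = DetectionRecord(
                            station_id=ch.detector_ids[k],
                            individual_id=None,
                            timestamp=seq_time,
                            profile_class="non_identifiable",
                            n_images=config.images_per_trigger,
                        )
                    else:
                        rec = DetectionRecord(
                            station_id=ch.detector_ids[k],
                            individual_id=ind,
                            timestamp=seq_time,
                            profile_class=profile_of[ind],
                            n_images=config.images_per_trigger,
                        )
                    records.append(rec)
                    if rng.random() < 0.3:
                        gap = 0.5  # immediate retrigger: merged by linking
                    else:
                        gap = float(rng.uniform(5.0, 60.0))
                    seq_time = seq_time + pd.Timedelta(seconds=gap)
                offset += rng.uniform(11.0, 120.0) * 60.0

    records.sort(key=lambda r: (r.station_id, r.timestamp))
    gen_events.sort(key=lambda e: (e.individual_id, e.station_id, e.timestamp))
    return records, config.detectors, gen_events, truth


def simulate_raw_stream(config: SimulationConfig, out_dir) -> Tuple[Path, Path]:
    """Write simulated raw data as the CSV pair the reader consumes.

    Returns (detection CSV path, detector layout CSV path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, detectors, _, _ = simulate_raw_records(config)
    det_path = write_detection_table(records, out_dir / "detections.csv")
    lay_path = write_detector_layout(detectors, out_dir / "detectors.csv")
    return det_path, lay_path
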