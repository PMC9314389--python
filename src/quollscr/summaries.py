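"""Descriptive survey summaries: accumulation curves, detection rates,
re-detection shares and cross-survey density tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import CaptHist, DetectionEvent, Survey
from .exceptions import ParameterError


def cumulative_curves(
    events_by_survey: Dict[str, Sequence[DetectionEvent]],
    surveys: Sequence[Survey],
) -> pd.DataFrame:
    """Mean cumulative detection and individual curves across surveys.

    For each survey, the per-night cumulative number of independent
    detections, and of distinct individuals first seen, are converted to
    percentages of that survey's totals; the mean and standard error over
    surveys are returned per night (columns ``night, mean_detections_pct,
    se_detections_pct, mean_individuals_pct, se_individuals_pct``).
    Surveys with zero detections are excluded with a warning.
    """
    surveys = list(surveys)
    if not surveys:
        raise ParameterError("no surveys supplied")
    n_nights = surveys[0].n_occasions
    if any(s.n_occasions != n_nights for s in surveys):
        raise ParameterError("all surveys must have the same number of nights")

    det_curves, ind_curves = [], []
    for s in surveys:
        evs = list(events_by_survey.get(s.survey_id, []))
        if not evs:
            warnings.warn(
                f"survey {s.survey_id!r} has zero detections; excluded from curves",
                stacklevel=2,
            )
            continue
        det = np.zeros(n_nights)
        ind = np.zeros(n_nights)
        seen = set()
        for ev in sorted(evs, key=lambda e: e.timestamp):
            occ = s.occasion_of(ev.timestamp)
            if occ is None:
                raise ParameterError(
                    f"event at {ev.timestamp} outside survey {s.survey_id!r}"
                )
            det[occ - 1] += 1
            if ev.individual_id not in seen:
                seen.add(ev.individual_id)
                ind[occ - 1] += 1
        det_curves.append(100.0 * np.cumsum(det) / det.sum())
        ind_curves.append(100.0 * np.cumsum(ind) / ind.sum())

    if not det_curves:
        raise ParameterError("every survey had zero detections")
    det_arr = np.vstack(det_curves)
    ind_arr = np.vstack(ind_curves)
    m = det_arr.shape[0]
    sem = lambda a: a.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(n_nights)
    return pd.DataFrame(
        {
            "night": np.arange(1, n_nights + 1),
            "mean_detections_pct": det_arr.mean(axis=0),
            "se_detections_pct": sem(det_arr),
            "mean_individuals_pct": ind_arr.mean(axis=0),
            "se_individuals_pct": sem(ind_arr),
        }
    )


def detections_per_100_nights(
    events: Sequence[DetectionEvent], effort: Dict[str, float]
) -> pd.Series:
    """Independent detections per 100 trap nights, by station.

    ``effort`` maps station_id to trap nights (nights the camera was
    active within the standardised surveys).  Stations listed in
    ``effort`` with no events get rate 0.0.
    """
    counts: Dict[str, int] = {s: 0 for s in effort}
    for ev in events:
        counts[ev.station_id] = counts.get(ev.station_id, 0) + 1
    rates = {}
    for station, n in counts.items():
        e = effort.get(station, 0.0)
        if e <= 0:
            if n > 0:
                raise ParameterError(
                    f"station {station!r} has {n} events but no recorded effort"
                )
            continue
        rates[station] = 100.0 * n / e
    return pd.Series(rates, name="detections_per_100_trap_nights").sort_index()


def redetection_stats(
    capthist: CaptHist, events: Sequence[DetectionEvent]
) -> Tuple[int, int, int, int]:
    """(n individuals, n events, % re-detected, % at >= 2 detectors).

    "% re-detected" is the share of individuals with at least two
    independent events; "% at >= 2 sites" the share detected at two or
    more distinct detectors (the spatial re-detections that inform
    sigma).  Percentages are rounded to integers for reporting.
    """
    n_ind = capthist.n_individuals
    n_events = len(events)
    if n_ind == 0:
        return 0, n_events, 0, 0
    per_ind: Dict[str, int] = {}
    for ev in events:
        per_ind[ev.individual_id] = per_ind.get(ev.individual_id, 0) + 1
    n_redetected = sum(1 for v in per_ind.values() if v >= 2)
    n_multi_site = capthist.n_spatial_redetections()
    pct_re = int(round(100.0 * n_redetected / n_ind))
    pct_ms = int(round(100.0 * n_multi_site / n_ind))
    return n_ind, n_events, pct_re, pct_ms


@dataclass(frozen=True)
class DensitySummary:
    """Cross-survey density summary (animals per km^2)."""

    estimates: tuple
    mean: float
    se_of_mean: float
    min: float
    max: float

    @property
    def n_surveys(self) -> int:
        return len(self.estimates)

    def rounded(self, decimals: int = 2) -> "DensitySummary":
        r = lambda v: round(v, decimals)
        return DensitySummary(
            estimates=tuple(r(e) for e in self.estimates),
            mean=r(self.mean), se_of_mean=r(self.se_of_mean),
            min=r(self.min), max=r(self.max),
        )

    def __str__(self):
        return (
            f"{self.mean:.2f} +/- {self.se_of_mean:.2f} (s.e.) per km^2, "
            f"range {self.min:.2f}-{self.max:.2f}, n = {self.n_surveys} surveys"
        )


def summarize_densities(estimates: Sequence[float]) -> DensitySummary:
    """Mean, s.e. (sd / sqrt(n)), min and max of per-survey densities."""
    vals = np.asarray(list(estimates), dtype=float)
    if vals.size < 2:
        raise ParameterError(
            f"need >= 2 per-survey estimates to summarise, got {vals.size}"
        )
    return DensitySummary(
        estimates=tuple(float(v) for v in vals),
        mean=float(vals.mean()),
        se_of_mean=float(vals.std(ddof=1) / np.sqrt(vals.size)),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def plot_cumulative_curves(curves: pd.DataFrame, path) -> None:
    """Write a cumulative-proportion figure (detections and individuals
    per night, with s.e. bands across surveys)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, se_col, label, color in [
        ("mean_individuals_pct", "se_individuals_pct", "individuals", "tab:blue"),
        ("mean_detections_pct", "se_detections_pct", "detections", "tab:gray"),
    ]:
        ax.plot(curves["night"], curves[col], label=label, color=color)
        ax.fill_between(
            curves["night"],
            curves[col] - curves[se_col],
            curves[col] + curves[se_col],
            alpha=0.25, color=color, linewidth=0,
        )
    ax.set_xlabel("survey night")
    ax.set_ylabel("cumulative proportion (%)")
    ax.set_ylim(0, 105)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
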