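"""Reading and writing the pipeline's tabular interchange formats.

Two input tables are consumed: a detection table (one row per identified
image sequence) and a detector layout (station coordinates in planar
metres).  Detection histories can be exported in the plain-text capture
format used throughout the SCR literature — one whitespace-separated row
per detection (``session animal_id occasion detector_id``) plus a detector
coordinate file — so histories built here can be cross-checked in other
SCR software.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .data import PROFILE_CLASSES, CaptHist, DetectionRecord, DetectorArray
from .exceptions import RowError, SchemaError

DETECTION_COLUMNS = ("station_id", "individual_id", "timestamp", "profile_class")
LAYOUT_COLUMNS = ("station_id", "x", "y")


def read_detection_table(path) -> List[DetectionRecord]:
    """Read a detection CSV into a sorted list of :class:`DetectionRecord`.

    Required columns: ``station_id, individual_id, timestamp, profile_class``
    (``n_images`` optional, default 10).  Timestamps must parse as ISO 8601.
    Exact duplicate rows are collapsed with a warning; records are returned
    sorted by (station_id, timestamp).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str, "individual_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    lines = np.arange(2, len(df) + 2)  # header is line 1

    dup_mask = df.duplicated(keep="first").to_numpy()
    if dup_mask.any():
        warnings.warn(
            f"{path.name}: collapsed {int(dup_mask.sum())} exact duplicate row(s)",
            stacklevel=2,
        )
        df = df[~dup_mask]
        lines = lines[~dup_mask]

    records = []
    for line, row in zip(lines, df.itertuples(index=False)):
        try:
            ts = pd.Timestamp(row.timestamp)
        except (ValueError, TypeError) as exc:
            raise RowError(
                f"unparseable timestamp {row.timestamp!r}", line=int(line)
            ) from exc
        if pd.isna(ts):
            raise RowError("missing timestamp", line=int(line))
        indiv = row.individual_id
        if pd.isna(indiv) or indiv == "":
            indiv = None
        n_images = int(getattr(row, "n_images", 10) or 10)
        pc = str(row.profile_class)
        if pc not in PROFILE_CLASSES:
            raise RowError(
                f"unknown profile_class {pc!r} (expected one of {PROFILE_CLASSES})",
                line=int(line),
            )
        try:
            records.append(
                DetectionRecord(
                    station_id=str(row.station_id),
                    individual_id=indiv,
                    timestamp=ts,
                    profile_class=pc,
                    n_images=n_images,
                )
            )
        except Exception as exc:
            raise RowError(str(exc), line=int(line)) from exc

    records.sort(key=lambda r: (r.station_id, r.timestamp))
    return records


def write_detection_table(records, path) -> Path:
    """Write records to CSV in the schema read by :func:`read_detection_table`."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "station_id": [r.station_id for r in records],
            "individual_id": [r.individual_id if r.individual_id is not None else "" for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
            "n_images": [r.n_images for r in records],
            "profile_class": [r.profile_class for r in records],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_detector_layout(path) -> DetectorArray:
    """Read a detector layout CSV (station_id, x, y; metres, planar)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise RowError(
                f"non-numeric {col} value {df.loc[bad[0], col]!r}",
                line=int(bad[0]) + 2,
            )
        df[col] = vals
    return DetectorArray(df["station_id"].tolist(), df[["x", "y"]].to_numpy())


def write_detector_layout(detectors: DetectorArray, path) -> Path:
    path = Path(path)
    detectors.as_dataframe().to_csv(path, index=False)
    return path


def export_capture_file(capthist: CaptHist, detectors: DetectorArray, path, session: str = "1") -> Path:
    """Export a detection history in the standard SCR capture text format.

    Writes one whitespace-separated row per detection
    (``session animal_id occasion detector_id``, occasions numbered from 1)
    to ``path``, and the detector layout to ``<path>.traps``.  The pair
    re-imports bit-identically via :func:`import_capture_file`.
    """
    path = Path(path)
    for sid in capthist.detector_ids:
        if sid not in detectors:
            raise SchemaError(f"capthist detector {sid!r} not in detector array")
    if capthist.n_individuals == 0:
        warnings.warn(f"{path.name}: capture history has zero individuals; "
                      "writing header-only file", stacklevel=2)
    with open(path, "w") as fh:
        fh.write("# session animal_id occasion detector_id\n")
        df = capthist.to_dataframe()
        for row in df.itertuples(index=False):
            fh.write(f"{session} {row.individual_id} {row.occasion} {row.detector_id}\n")
    trap_path = path.with_suffix(path.suffix + ".traps")
    with open(trap_path, "w") as fh:
        fh.write("# detector_id x y\n")
        for sid, (x, y) in zip(detectors.station_ids, detectors.xy):
            fh.write(f"{sid} {x:.10g} {y:.10g}\n")
    return path


def import_capture_file(path, n_occasions: int, detectors: DetectorArray | None = None) -> CaptHist:
    """Re-import a capture file written by :func:`export_capture_file`.

    ``n_occasions`` must be supplied because a capture file lists only the
    occasions on which detections occurred.  If ``detectors`` is None the
    accompanying ``<path>.traps`` file is read for the detector ordering.
    """
    path = Path(path)
    if detectors is None:
        trap_path = path.with_suffix(path.suffix + ".traps")
        rows = []
        with open(trap_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                sid, x, y = line.split()
                rows.append((sid, float(x), float(y)))
        detectors = DetectorArray([r[0] for r in rows], [(r[1], r[2]) for r in rows])
    dets = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, animal, occ, det = line.split()
            dets.append((animal, int(occ), det))
    individuals = sorted({d[0] for d in dets})
    idx = {a: i for i, a in enumerate(individuals)}
    inc = np.zeros((len(individuals), n_occasions, detectors.n), dtype=np.uint8)
    for animal, occ, det in dets:
        inc[idx[animal], occ - 1, detectors.index(det)] = 1
    return CaptHist(individuals, detectors.station_ids, inc)
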