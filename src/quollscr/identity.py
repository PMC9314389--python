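"""Individual-identification bookkeeping.

Identity in this pipeline is carried by catalogue tags assigned during
manual photo review: every image sequence either matches a profiled
individual (complete or single-side "semi" profile) or is
non-identifiable.  This module implements the mechanical rules around
those tags — linking immediately consecutive sequences, choosing which
lateral side's semi profiles enter the analysis at each site, and the
per-study assignment summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, List, Optional

import pandas as pd

from .data import DetectionRecord, ProfileCatalogue
from .exceptions import IdentityConflictError

#: maximum gap (seconds) between successive sequences treated as one trigger burst
LINK_GAP_SECONDS = 1.0


def link_sequences(records: List[DetectionRecord]) -> List[DetectionRecord]:
    """Merge immediately consecutive sequences at the same station.

    A camera on rapid-fire re-triggers with essentially no delay while an
    animal stays in frame, so successive sequences separated by < 1 s are
    one encounter and share one identification tag.  The merged record
    keeps the earliest timestamp and the summed image count; a tagged
    sequence donates its tag to an untagged (non-identifiable) neighbour.

    Raises
    ------
    IdentityConflictError
        If two linked sequences carry different non-null tags.
    """
    out: List[DetectionRecord] = []
    for rec in sorted(records, key=lambda r: (r.station_id, r.timestamp)):
        if out:
            prev = out[-1]
            gap = (rec.timestamp - prev.timestamp).total_seconds()
            if rec.station_id == prev.station_id and 0 <= gap < LINK_GAP_SECONDS:
                if (
                    prev.individual_id is not None
                    and rec.individual_id is not None
                    and prev.individual_id != rec.individual_id
                ):
                    raise IdentityConflictError(
                        f"sequences at {rec.station_id} {prev.timestamp} / "
                        f"{rec.timestamp} linked but tagged "
                        f"{prev.individual_id!r} and {rec.individual_id!r}"
                    )
                tagged = prev if prev.individual_id is not None else rec
                out[-1] = replace(
                    prev,
                    individual_id=tagged.individual_id,
                    profile_class=tagged.profile_class,
                    n_images=prev.n_images + rec.n_images,
                )
                continue
        out.append(rec)
    return out


def select_lateral_side(catalogue: ProfileCatalogue) -> str:
    """Choose which lateral side's semi-complete profiles enter the analysis.

    A left-only and a right-only profile could be the same animal, so only
    one side may be counted alongside the complete profiles.  The side with
    more semi-complete profiles at the site is kept (it loses the fewest
    individuals); ties and the no-semi-profile case default to "left" with
    a warning.  The choice is recorded on the catalogue.
    """
    n_left, n_right = catalogue.side_counts()
    if n_left > n_right:
        side = "left"
    elif n_right > n_left:
        side = "right"
    else:
        side = "left"
        warnings.warn(
            f"site {catalogue.site!r}: lateral-side counts tied or absent "
            f"(left={n_left}, right={n_right}); defaulting to left",
            stacklevel=2,
        )
    catalogue.chosen_side = side
    return side


def apply_side_selection(
    records: Iterable[DetectionRecord], side: str
) -> List[DetectionRecord]:
    """Drop records of semi profiles from the non-chosen lateral side.

    Complete-profile and non-identifiable records always pass through.
    """
    excluded = "semi_right" if side == "left" else "semi_left"
    return [r for r in records if r.profile_class != excluded]


def summarize_assignments(
    records: Iterable[DetectionRecord], study: Optional[str] = None
) -> pd.DataFrame:
    """Tabulate sequence-assignment outcomes for one study.

    Returns one row with the total number of sequences and the counts and
    percentages (1 decimal) assigned to complete profiles, to semi
    (single-side) profiles, and left non-identifiable.  An empty record
    list yields an empty table.
    """
    records = list(records)
    cols = [
        "study", "n_sequences",
        "n_complete", "pct_complete",
        "n_semi", "pct_semi",
        "n_non_identifiable", "pct_non_identifiable",
    ]
    if not records:
        return pd.DataFrame(columns=cols)
    total = len(records)
    n_complete = sum(r.profile_class == "complete" for r in records)
    n_semi = sum(r.profile_class in ("semi_left", "semi_right") for r in records)
    n_nonid = sum(r.profile_class == "non_identifiable" for r in records)
    row = {
        "study": study if study is not None else "",
        "n_sequences": total,
        "n_complete": n_complete,
        "pct_complete": round(100.0 * n_complete / total, 1),
        "n_semi": n_semi,
        "pct_semi": round(100.0 * n_semi / total, 1),
        "n_non_identifiable": n_nonid,
        "pct_non_identifiable": round(100.0 * n_nonid / total, 1),
    }
    return pd.DataFrame([row], columns=cols)
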