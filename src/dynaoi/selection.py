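"""Two-session, three-criterion AOI selection pipeline.

AOIs defined for a hazard-perception test should capture *deliberate* gaze
behavior.  Pilot data from normally sighted participants, collected in two
measurement sessions (T1, T2), is used to weed out AOIs that cannot do so.
Per session, an AOI is flagged for exclusion when any of three criteria
holds:

1. **Low viewership** — fewer than ``min_viewers`` participants ever
   looked at it (it is not where experienced drivers look);
2. **Central onset** — its (margin-inflated) onset box touches the central
   10-degree disc of the screen, so it is hit "for free" by anyone watching
   the road ahead;
3. **Fast entry from the central band** — its onset box touches the
   10–30-degree band and the cohort's median entry time is below the
   natural saccade-latency floor (120 ms), implying the first "hits" were
   not deliberate saccades.

An AOI is finally excluded only when it was flagged in *both* sessions;
a single-session flag is treated as noise.  An overrides table can
re-decide individual AOIs (the rule is "generally marked for exclusion" —
panel discretion is an input, never auto-applied).

The report mirrors the bookkeeping of a per-object-class selection table:
counts per criterion per session, final exclusions, and remaining AOIs,
with conservation (before − excluded = remaining) guaranteed per class and
in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .data_io import AOITrack
from .geometry import ScreenConfig, central_radius_px
from .metrics import inflate

ZONES = ("CORE", "BAND", "PERIPHERY")

REPORT_COLUMNS = [
    "object_class",
    "n_before",
    "c2_core_T1",
    "c2_core_T2",
    "c1_low_viewers_T1",
    "c1_low_viewers_T2",
    "c3_fast_entry_T1",
    "c3_fast_entry_T2",
    "excluded",
    "remaining",
]


@dataclass(frozen=True)
class SelectionThresholds:
    """Tunable thresholds of the selection pipeline.

    ``min_viewers`` is an absolute participant count (default 10, i.e. half
    of a 20-participant cohort); set ``half_of_cohort=True`` to derive it
    per session as ``ceil(n_participants / 2)`` instead.  The central zones
    are angular *diameters*; ``min_median_entry_s`` is the saccade-latency
    floor below which a median entry time cannot reflect deliberate gaze.
    """

    min_viewers: int = 10
    central_core_deg: float = 10.0
    central_band_deg: float = 30.0
    min_median_entry_s: float = 0.120
    half_of_cohort: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.central_core_deg < self.central_band_deg:
            raise ValueError("need 0 < central_core_deg < central_band_deg")
        if self.min_median_entry_s < 0:
            raise ValueError("min_median_entry_s must be >= 0")

    def viewers_threshold(self, n_participants: int | None = None) -> int:
        if self.half_of_cohort:
            if n_participants is None:
                raise ValueError("half_of_cohort mode needs n_participants")
            return ceil(n_participants / 2)
        return self.min_viewers


@dataclass(frozen=True)
class SessionAOIStats:
    """Per-AOI, per-session cohort aggregates."""

    aoi_id: str
    session: str
    n_viewed: int
    median_entry: float | None
    n_participants: int | None = None


@dataclass(frozen=True)
class SessionFlags:
    c1_low_viewers: bool
    c2_core_onset: bool
    c3_band_fast_entry: bool

    @property
    def flagged(self) -> bool:
        return self.c1_low_viewers or self.c2_core_onset or self.c3_band_fast_entry


@dataclass(frozen=True)
class ExclusionRecord:
    """Full two-session audit trail for one AOI."""

    aoi_id: str
    flags_T1: SessionFlags
    flags_T2: SessionFlags
    final: str  # KEEP or EXCLUDE
    overridden: bool = False


def _rect_intersects_disc(rect, center: tuple[float, float], radius_px: float) -> bool:
    # Closest point of the rectangle to the disc center.
    qx = min(max(center[0], rect.x1), rect.x2)
    qy = min(max(center[1], rect.y1), rect.y2)
    return (qx - center[0]) ** 2 + (qy - center[1]) ** 2 <= radius_px**2


def onset_zone(
    track: AOITrack, cfg: ScreenConfig, th: SelectionThresholds,
    margin_mode: str = "local",
) -> str:
    """Classify where an AOI *starts*: CORE, BAND, or PERIPHERY.

    The margin-inflated onset box is intersected with the central discs
    (not just its center point): an AOI whose inflated footprint overlaps
    the core disc is hit "for free" by central gaze even if its center is
    eccentric, which is the phenomenon the core criterion targets.  On the
    flat-plane model each disc of angular diameter D is an exact pixel
    circle of radius tan(D/2)·distance.
    """
    box = inflate(track.onset_box, track.margin_deg, cfg, mode=margin_mode)
    center = cfg.center
    if _rect_intersects_disc(box, center, central_radius_px(th.central_core_deg, cfg)):
        return "CORE"
    if _rect_intersects_disc(box, center, central_radius_px(th.central_band_deg, cfg)):
        return "BAND"
    return "PERIPHERY"


def evaluate_session(
    stats: SessionAOIStats, zone: str, th: SelectionThresholds
) -> SessionFlags:
    """Apply the three per-session exclusion criteria."""
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}")
    c1 = stats.n_viewed < th.viewers_threshold(stats.n_participants)
    c2 = zone == "CORE"
    c3 = (
        zone == "BAND"
        and stats.median_entry is not None
        and stats.median_entry < th.min_median_entry_s
    )
    return SessionFlags(c1, c2, c3)


def final_decision(flags_T1: SessionFlags, flags_T2: SessionFlags) -> str:
    """EXCLUDE only when both sessions flagged the AOI; otherwise KEEP."""
    return "EXCLUDE" if (flags_T1.flagged and flags_T2.flagged) else "KEEP"


_NOT_FLAGGED = SessionFlags(False, False, False)


def run_selection(
    tracks: list[AOITrack],
    stats_by_session: dict[str, dict[str, SessionAOIStats]],
    cfg: ScreenConfig,
    th: SelectionThresholds,
    overrides: dict[str, str] | None = None,
    margin_mode: str = "local",
) -> list[ExclusionRecord]:
    """Evaluate every AOI across both sessions and decide KEEP/EXCLUDE.

    ``stats_by_session`` maps session ("T1"/"T2") to ``{aoi_id: stats}``.
    An AOI absent from a session (e.g. participant dropout left no data)
    is treated as not-flagged in that session.  ``overrides`` maps aoi_id
    to a forced final decision.
    """
    overrides = overrides or {}
    records = []
    for tr in tracks:
        zone = onset_zone(tr, cfg, th, margin_mode)
        flags = {}
        for session in ("T1", "T2"):
            st = stats_by_session.get(session, {}).get(tr.aoi_id)
            flags[session] = (
                evaluate_session(st, zone, th) if st is not None else _NOT_FLAGGED
            )
        final = final_decision(flags["T1"], flags["T2"])
        overridden = tr.aoi_id in overrides
        if overridden:
            forced = overrides[tr.aoi_id]
            if forced not in ("KEEP", "EXCLUDE"):
                raise ValueError(f"override for {tr.aoi_id} must be KEEP or EXCLUDE")
            final = forced
        records.append(
            ExclusionRecord(tr.aoi_id, flags["T1"], flags["T2"], final, overridden)
        )
    return records


def selection_report(
    records: list[ExclusionRecord], tracks: list[AOITrack]
) -> pd.DataFrame:
    """Per-object-class selection bookkeeping plus a totals row.

    Columns: AOIs before selection; per-session counts of the core-onset,
    low-viewership, and fast-entry criteria; final exclusions (both-session
    rule); and remaining AOIs.  ``before - excluded = remaining`` holds per
    class and in total by construction.
    """
    by_id = {r.aoi_id: r for r in records}
    missing = [tr.aoi_id for tr in tracks if tr.aoi_id not in by_id]
    if missing:
        raise ValueError(f"AOIs without exclusion record: {', '.join(missing)}")
    rows = {}
    for tr in tracks:
        r = by_id[tr.aoi_id]
        row = rows.setdefault(
            tr.object_class, {c: 0 for c in REPORT_COLUMNS if c != "object_class"}
        )
        row["n_before"] += 1
        for session in ("T1", "T2"):
            f: SessionFlags = getattr(r, f"flags_{session}")
            row[f"c2_core_{session}"] += f.c2_core_onset
            row[f"c1_low_viewers_{session}"] += f.c1_low_viewers
            row[f"c3_fast_entry_{session}"] += f.c3_band_fast_entry
        excluded = r.final == "EXCLUDE"
        row["excluded"] += excluded
        row["remaining"] += not excluded
    table = pd.DataFrame(
        [{"object_class": k, **v} for k, v in sorted(rows.items())],
        columns=REPORT_COLUMNS,
    )
    total = table.drop(columns="object_class").sum()
    total["object_class"] = "total"
    table = pd.concat([table, total.to_frame().T], ignore_index=True)
    return table[REPORT_COLUMNS]
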