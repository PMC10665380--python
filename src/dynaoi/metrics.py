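"""AOI hit, entry-time, dwell-time, and screen-region dwell metrics.

An *AOI hit* is a valid gaze sample whose point falls inside the AOI's
margin-inflated bounding box while the AOI is on screen.  From hits follow:

* **entry time** — seconds from the AOI's onset (first appearance) to the
  first hit; 0 when gaze is already inside the inflated box at onset;
* **dwell time** — total seconds of hit samples over the AOI's lifetime;
* **viewed** — whether any hit occurred.

Cohort statistics use the *median* entry time across the participants who
viewed the AOI, because entry-time distributions are strongly right-skewed.

Screen-region dwell ratios divide the valid time spent in each region by
the **total video length**, not by valid time — so the entire-screen ratio
doubles as the valid-observation fraction of the recording (blinks and
look-aways pull it below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import (
    AOITrack,
    GazeRecording,
    Rect,
    ValidityPolicy,
    boxes_at,
    sample_durations,
    valid_mask,
)
from .geometry import (
    REGION_LABELS,
    ScreenConfig,
    deg_to_px,
    eccentricity_deg,
    region_masks,
)


@dataclass(frozen=True)
class EntryResult:
    """Per-recording outcome for one AOI."""

    viewed: bool
    entry_time: float | None  # seconds from AOI onset; None if never viewed
    dwell_time: float  # seconds inside the inflated AOI


@dataclass(frozen=True)
class RegionRatios:
    """Time-in-region ratios, each relative to total video length."""

    central10: float
    central20: float
    central30: float
    entire_screen: float
    left: float
    right: float
    top: float
    bottom: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in REGION_LABELS}


def inflate(box: Rect, margin_deg: float, cfg: ScreenConfig,
            mode: str = "local") -> Rect:
    """Expand a box outward by an angular margin converted to pixels.

    The margin compensates for eye-tracker inaccuracy: a gaze sample within
    ``margin_deg`` of the box should still count as a hit.  In ``local``
    mode the degree-to-pixel conversion is evaluated at the box center, so
    a margin subtends the stated angle even at high eccentricity where a
    degree spans more pixels.  ``central`` mode uses the screen-center
    conversion everywhere (the constant-pixel behavior of simpler tools).

    The result is clipped to the screen bounds extended by one margin, so
    inflated rectangles stay finite while never clipping away legitimately
    reachable area just off the edge.
    """
    if margin_deg < 0:
        raise ValueError("margin_deg must be >= 0")
    if margin_deg == 0:
        return box
    at = box.center if mode == "local" else None
    try:
        m = deg_to_px(margin_deg, cfg, at=at)
    except Exception:
        # Box center beyond the representable eccentricity: fall back to the
        # central conversion rather than failing on a pathological track.
        m = deg_to_px(margin_deg, cfg)
    lo_x, lo_y = -m, -m
    hi_x, hi_y = cfg.width_px + m, cfg.height_px + m
    return Rect(
        max(box.x1 - m, lo_x),
        max(box.y1 - m, lo_y),
        min(box.x2 + m, hi_x),
        min(box.y2 + m, hi_y),
    )


def hit_mask(
    rec: GazeRecording,
    track: AOITrack,
    cfg: ScreenConfig,
    policy: ValidityPolicy,
    margin_mode: str = "local",
) -> np.ndarray:
    """Per-sample hit flags: valid AND AOI present AND inside inflated box.

    Boundaries are closed — a point exactly on the inflated edge counts as
    inside (a deterministic tie rule).
    """
    ok = valid_mask(rec, policy, cfg)
    present, corners = boxes_at(track, rec.t)
    hits = ok & present
    if not hits.any():
        return hits
    m = np.zeros(len(rec))
    if track.margin_deg > 0:
        if margin_mode == "local":
            bcx = (corners[:, 0] + corners[:, 2]) / 2.0
            bcy = (corners[:, 1] + corners[:, 3]) / 2.0
            ecc = eccentricity_deg(bcx, bcy, cfg)
            # Degenerate eccentricities (box center beyond the representable
            # angle) fall back to the central conversion.
            ecc = np.where(ecc + track.margin_deg >= 90.0, 0.0, ecc)
        else:
            ecc = np.zeros(len(rec))
        d_cm = cfg.viewing_distance_cm
        m = (
            np.tan(np.radians(ecc + track.margin_deg)) - np.tan(np.radians(ecc))
        ) * d_cm * cfg.px_per_cm
    # Inflated corners, clipped to screen bounds extended by one margin.
    x1 = np.maximum(corners[:, 0] - m, -m)
    y1 = np.maximum(corners[:, 1] - m, -m)
    x2 = np.minimum(corners[:, 2] + m, cfg.width_px + m)
    y2 = np.minimum(corners[:, 3] + m, cfg.height_px + m)
    inside = (rec.x >= x1) & (rec.x <= x2) & (rec.y >= y1) & (rec.y <= y2)
    return hits & inside


def hit_intervals(
    rec: GazeRecording,
    track: AOITrack,
    cfg: ScreenConfig,
    policy: ValidityPolicy,
    margin_mode: str = "local",
) -> list[tuple[float, float]]:
    """Merge consecutive hit samples into (start, end) intervals in seconds.

    Each hit sample contributes the interval it owns (see
    :func:`dynaoi.data_io.sample_durations`); runs of consecutive hit
    samples merge into one interval, clamped to the AOI's lifetime.
    """
    hits = hit_mask(rec, track, cfg, policy, margin_mode)
    if not hits.any():
        return []
    dur = sample_durations(rec)
    intervals = []
    idx = np.nonzero(hits)[0]
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            intervals.append((run_start, prev))
            run_start = i
        prev = i
    intervals.append((run_start, prev))
    out = []
    for i0, i1 in intervals:
        start = max(rec.t[i0], track.onset)
        end = min(rec.t[i1] + dur[i1], track.offset)
        if end > start:
            out.append((float(start), float(end)))
    return out


def entry_and_dwell(
    rec: GazeRecording,
    track: AOITrack,
    cfg: ScreenConfig,
    policy: ValidityPolicy,
    margin_mode: str = "local",
) -> EntryResult:
    """Entry time, dwell time, and viewed flag for one recording x AOI.

    Entry time is measured from AOI onset to the first hit sample's
    timestamp with no sub-sample interpolation (tracker noise dominates
    below one sample interval); gaze already inside at onset yields 0.
    """
    ivs = hit_intervals(rec, track, cfg, policy, margin_mode)
    if not ivs:
        return EntryResult(viewed=False, entry_time=None, dwell_time=0.0)
    entry = max(ivs[0][0] - track.onset, 0.0)
    dwell = float(sum(e - s for s, e in ivs))
    return EntryResult(viewed=True, entry_time=float(entry), dwell_time=dwell)


def cohort_aoi_stats(
    recs: list[GazeRecording],
    track: AOITrack,
    cfg: ScreenConfig,
    policy: ValidityPolicy,
    margin_mode: str = "local",
) -> tuple[int, float | None]:
    """Viewer count and median entry time for one AOI over a cohort.

    The median is taken over the participants who viewed the AOI
    (non-viewers have no entry time and are excluded); even counts use the
    midpoint convention.  Returns ``(0, None)`` when nobody viewed it.
    """
    if not recs:
        raise ValueError("need at least one recording")
    entries = []
    for rec in recs:
        r = entry_and_dwell(rec, track, cfg, policy, margin_mode)
        if r.viewed:
            entries.append(r.entry_time)
    if not entries:
        return 0, None
    return len(entries), float(np.median(entries))


def region_ratios(
    rec: GazeRecording, cfg: ScreenConfig, policy: ValidityPolicy
) -> RegionRatios:
    """Time-in-region ratios with total video length as denominator.

    ``ratio(region) = sum of valid-sample durations in region / video_duration``.
    Invalid time (blinks, look-aways) counts toward no region, which is why
    ``entire_screen`` equals the valid-time fraction rather than 1.
    """
    if rec.video_duration <= 0:
        raise ValueError("video_duration must be positive")
    ok = valid_mask(rec, policy, cfg)
    dur = sample_durations(rec) * ok
    masks = region_masks(rec.x, rec.y, cfg)
    vals = {
        name: float(np.sum(dur[mask]) / rec.video_duration)
        for name, mask in masks.items()
    }
    return RegionRatios(**vals)


def metrics_table(
    recs: list[GazeRecording],
    tracks: list[AOITrack],
    cfg: ScreenConfig,
    policy: ValidityPolicy,
    margin_mode: str = "local",
) -> pd.DataFrame:
    """One row per (recording x AOI) with viewed/entry/dwell columns."""
    rows = []
    for rec in recs:
        for tr in tracks:
            r = entry_and_dwell(rec, tr, cfg, policy, margin_mode)
            rows.append(
                (
                    rec.participant_id,
                    rec.session,
                    rec.video_id,
                    tr.aoi_id,
                    r.viewed,
                    r.entry_time if r.entry_time is not None else np.nan,
                    r.dwell_time,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "session",
            "video_id",
            "aoi_id",
            "viewed",
            "entry_time_s",
            "dwell_time_s",
        ],
    )


def region_table(
    recs: list[GazeRecording], cfg: ScreenConfig, policy: ValidityPolicy
) -> pd.DataFrame:
    """One row per recording with the eight region ratios."""
    rows = []
    for rec in recs:
        rr = region_ratios(rec, cfg, policy)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "session": rec.session,
                "video_id": rec.video_id,
                **rr.as_dict(),
            }
        )
    return pd.DataFrame(rows)
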