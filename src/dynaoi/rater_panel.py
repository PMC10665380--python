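"""Aggregation of multi-rater object annotations into AOI decisions.

A panel of raters (default 10) marks candidate objects in each video and
assigns each a category: MUST_BE_SEEN (the driver must act — brake, change
lanes, delay acceleration) or MAY_BE_SEEN (relevant to notice, no action
required).  Aggregation rules:

* an object chosen by >= 5 raters is included;
* exactly 4 votes sends it to panel review (resolved externally);
* <= 3 votes excludes it;
* traffic lights are always included, regardless of votes;
* the category is the majority of the voters' category votes, with a
  configurable tie-break (default MUST_BE_SEEN — the conservative choice
  for a hazard-perception test).

A state change in a tracked object (a traffic light changing color, brake
lights activating) starts a *new* AOI: :func:`split_on_state_change` cuts a
track into abutting children at the event times.

Rater mouse clicks can also be rendered as a 2-D screen heatmap with
marginal histograms to visualise where the panel's attention concentrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .data_io import AOITrack, Rect, box_at
from .geometry import ScreenConfig, on_surface

logger = logging.getLogger(__name__)

DECISIONS = ("INCLUDE", "PANEL_REVIEW", "EXCLUDE")

#: Vote thresholds: include at or above, review exactly at.
INCLUDE_VOTES = 5
REVIEW_VOTES = 4


@dataclass(frozen=True)
class RaterVote:
    rater_id: str
    object_id: str
    category_vote: str  # MUST_BE_SEEN or MAY_BE_SEEN


@dataclass(frozen=True)
class RaterClick:
    rater_id: str
    t: float
    x: float
    y: float
    category_vote: str


@dataclass(frozen=True)
class AOIDecision:
    object_id: str
    n_votes: int
    decision: str
    category: str
    forced: bool  # traffic-light override applied


def decide_inclusion(
    votes: list[RaterVote],
    n_raters: int = 10,
    is_traffic_light: bool = False,
    tie_category: str = "MUST_BE_SEEN",
) -> AOIDecision:
    """Apply the panel's inclusion rules to one object's votes.

    ``votes`` are the votes cast *for* this object (one per rater).  A
    traffic light is included unconditionally and marked ``forced``; with
    no voters its category defaults to MUST_BE_SEEN.
    """
    n = len(votes)
    if n > n_raters:
        raise ValueError(f"{n} votes exceed panel size {n_raters}")
    if len({v.rater_id for v in votes}) != n:
        raise ValueError("duplicate rater in vote set")
    object_id = votes[0].object_id if votes else ""
    if any(v.object_id != object_id for v in votes):
        raise ValueError("votes span multiple objects")

    must = sum(v.category_vote == "MUST_BE_SEEN" for v in votes)
    may = n - must
    if must > may:
        category = "MUST_BE_SEEN"
    elif may > must:
        category = "MAY_BE_SEEN"
    else:
        category = tie_category

    if is_traffic_light:
        return AOIDecision(object_id, n, "INCLUDE",
                           category if n else "MUST_BE_SEEN", forced=True)
    if n >= INCLUDE_VOTES:
        decision = "INCLUDE"
    elif n == REVIEW_VOTES:
        decision = "PANEL_REVIEW"
    else:
        decision = "EXCLUDE"
    return AOIDecision(object_id, n, decision, category, forced=False)


def split_on_state_change(
    track: AOITrack, event_times: list[float]
) -> list[AOITrack]:
    """Split a track into abutting child AOIs at state-change events.

    Event times are snapped to the nearest integer frame so children stay
    on the track's frame grid; events outside the open lifetime (or
    snapping onto an endpoint) are ignored with a warning.  Child ids are
    ``{parent}#k``; consecutive children share the boundary keyframe, so
    the children's lifetimes tile the parent's exactly and per-frame
    geometry is preserved (boundary boxes are synthesized by
    interpolation).
    """
    first = track.keyframes[0][0]
    last = track.keyframes[-1][0]
    cut_frames: list[float] = []
    for t in event_times:
        f = round(t * track.fps)
        if f <= first or f >= last:
            logger.warning(
                "event at t=%.3fs outside lifetime of %s; ignored", t, track.aoi_id
            )
            continue
        if f not in cut_frames:
            cut_frames.append(f)
    if not cut_frames:
        return [track]
    cut_frames.sort()

    bounds = [first, *cut_frames, last]
    frames = [f for f, _ in track.keyframes]
    children = []
    for k, (a, b) in enumerate(zip(bounds, bounds[1:])):
        kfs = []
        if a not in frames:
            kfs.append((float(a), box_at(track, a / track.fps)))
        kfs.extend((f, box) for f, box in track.keyframes if a <= f <= b)
        if b not in frames:
            kfs.append((float(b), box_at(track, b / track.fps)))
        kfs.sort(key=lambda kb: kb[0])
        children.append(
            replace(track, aoi_id=f"{track.aoi_id}#{k}", keyframes=tuple(kfs))
        )
    return children


def click_heatmap(
    clicks: list[RaterClick],
    cfg: ScreenConfig,
    bins: tuple[int, int] = (96, 20),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D count grid of on-surface clicks plus x/y marginal histograms.

    Returns ``(grid, x_marginal, y_marginal)`` where ``grid[ix, iy]`` counts
    clicks in the corresponding screen cell (x bins first), and the
    marginals are the row/column sums.  Grid counts sum to the number of
    on-surface clicks; off-surface clicks are dropped.
    """
    nx, ny = bins
    if nx < 1 or ny < 1:
        raise ValueError("need at least one bin per axis")
    x = np.array([c.x for c in clicks], dtype=float)
    y = np.array([c.y for c in clicks], dtype=float)
    if len(clicks):
        keep = on_surface(x, y, cfg)
        x, y = x[keep], y[keep]
    grid, _, _ = np.histogram2d(
        x, y, bins=[nx, ny], range=[[0, cfg.width_px], [0, cfg.height_px]]
    )
    return grid, grid.sum(axis=1), grid.sum(axis=0)
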