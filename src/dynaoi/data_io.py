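"""Gaze-recording and dynamic-AOI track I/O, validity, and time accounting.

Gaze streams arrive as surface-mapped exports: one CSV per participant x
session x video with columns ``timestamp,x_norm,y_norm,confidence,on_surf``.
Normalized coordinates use the surface convention with the origin at the
bottom-left; ingestion flips them to the package's top-left image convention
and scales to pixels.

Dynamic AOI tracks are frame-indexed bounding boxes with a category
(MUST_BE_SEEN / MAY_BE_SEEN) and an object class, stored as CSV with a
``#format=1`` version header.  Between keyframes, boxes are linearly
interpolated (exact at keyframes); a track exists from its first keyframe
(onset) to its last (offset).

Time accounting: each gaze sample owns the interval up to the next sample's
timestamp, so dwell and ratio computations are robust to irregular sampling
and dropped frames.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ScreenConfig, on_surface

AOI_FORMAT_VERSION = 1

#: Expert categories for rated objects.
CATEGORIES = ("MUST_BE_SEEN", "MAY_BE_SEEN")

#: Object classes occurring in the traffic-scene annotation scheme.
OBJECT_CLASSES = (
    "ambulance",
    "barricade",
    "bus",
    "car",
    "cyclist",
    "motorcycle",
    "pedestrian",
    "police",
    "sign",
    "traffic_light",
    "tram",
    "truck",
    "van",
)

GAZE_COLUMNS = ("timestamp", "x_norm", "y_norm", "confidence", "on_surf")
AOI_COLUMNS = ("aoi_id", "category", "object_class", "frame", "x1", "y1", "x2", "y2")


class FormatError(ValueError):
    """Malformed input file (missing column, bad version, empty stream)."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle with x1 < x2, y1 < y2."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    def contains(self, x, y):
        """Closed-boundary containment; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x1) & (x <= self.x2) & (y >= self.y1) & (y <= self.y2)


@dataclass(frozen=True)
class ValidityPolicy:
    """Which gaze samples count as valid observation time.

    Samples below ``min_confidence`` (blinks, tracking loss) or off the
    surface are excluded from all metrics.  The 0.6 confidence default is
    the conventional threshold for pupil-detection confidence streams.
    """

    min_confidence: float = 0.6
    require_on_surface: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError(f"min_confidence must be in [0,1], got {self.min_confidence}")


@dataclass
class GazeRecording:
    """One participant x session x video stream of screen-mapped gaze samples.

    Samples are stored as parallel numpy arrays sorted by time; ``t`` is in
    seconds from video start.
    """

    participant_id: str
    session: str  # "T1" or "T2"
    video_id: str
    video_duration: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    on_surf: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.on_surf = np.asarray(self.on_surf, dtype=bool)
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.confidence, self.on_surf)):
            raise ValueError("sample arrays must have equal length")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample timestamps must be strictly increasing")
        if n and (self.t[0] < 0 or self.t[-1] > self.video_duration):
            raise ValueError("timestamps must lie within [0, video_duration]")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class AOITrack:
    """One dynamic area of interest: frame-indexed boxes plus metadata.

    ``keyframes`` is a sequence of ``(frame_index, Rect)`` pairs, strictly
    increasing in frame index.  Frame ``k`` covers video time
    ``[k/fps, (k+1)/fps)``; the AOI exists on ``[onset, offset]`` where
    onset/offset are the first/last keyframe times.  ``margin_deg`` is the
    angular margin added around the box to absorb tracker inaccuracy.
    """

    aoi_id: str
    category: str
    object_class: str
    keyframes: tuple[tuple[float, Rect], ...]
    fps: float = 25.0
    margin_deg: float = 2.5

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.keyframes:
            raise ValueError("track needs at least one keyframe")
        frames = [f for f, _ in self.keyframes]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("keyframes must be strictly increasing in frame index")

    @property
    def onset(self) -> float:
        """First-appearance time in seconds."""
        return self.keyframes[0][0] / self.fps

    @property
    def offset(self) -> float:
        """Disappearance time in seconds."""
        return self.keyframes[-1][0] / self.fps

    @property
    def onset_box(self) -> Rect:
        return self.keyframes[0][1]


def read_gaze(
    path,
    cfg: ScreenConfig,
    *,
    participant_id: str = "",
    session: str = "T1",
    video_id: str = "",
    video_duration: float | None = None,
) -> GazeRecording:
    """Read a surface-mapped gaze CSV into a :class:`GazeRecording`.

    Normalized coordinates are scaled to pixels and the y axis is flipped
    from the surface's bottom-left convention to top-left.  Rows are sorted
    by timestamp; duplicate timestamps keep the last occurrence (matching
    streaming-export behavior where later rows supersede earlier ones).
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze file {path} missing column(s): {', '.join(missing)}")
    if df.empty:
        raise FormatError(f"gaze file {path} contains no samples")
    df = df.sort_values("timestamp", kind="stable").drop_duplicates(
        "timestamp", keep="last"
    )
    t = df["timestamp"].to_numpy(dtype=float)
    if video_duration is None:
        video_duration = float(t[-1])
    return GazeRecording(
        participant_id=participant_id,
        session=session,
        video_id=video_id,
        video_duration=float(video_duration),
        t=t,
        x=df["x_norm"].to_numpy(dtype=float) * cfg.width_px,
        y=(1.0 - df["y_norm"].to_numpy(dtype=float)) * cfg.height_px,
        confidence=df["confidence"].to_numpy(dtype=float),
        on_surf=df["on_surf"].to_numpy(dtype=bool),
    )


def write_gaze(rec: GazeRecording, path, cfg: ScreenConfig) -> None:
    """Write a recording back to the normalized gaze CSV dialect."""
    pd.DataFrame(
        {
            "timestamp": rec.t,
            "x_norm": rec.x / cfg.width_px,
            "y_norm": 1.0 - rec.y / cfg.height_px,
            "confidence": rec.confidence,
            "on_surf": rec.on_surf,
        }
    ).to_csv(path, index=False)


def valid_mask(rec: GazeRecording, policy: ValidityPolicy, cfg: ScreenConfig) -> np.ndarray:
    """Boolean per-sample validity under the policy.

    A sample is valid when its confidence clears the threshold, it is
    flagged on-surface (if required), and its point lies within the screen
    bounds.  Blinks and look-aways fail this test and contribute no
    observation time.
    """
    ok = rec.confidence >= policy.min_confidence
    if policy.require_on_surface:
        ok = ok & rec.on_surf
    return ok & on_surface(rec.x, rec.y, cfg)


def sample_durations(rec: GazeRecording, nominal_dt: float | None = None) -> np.ndarray:
    """Seconds of video time owned by each sample.

    Each sample owns the interval up to the next sample's timestamp.  The
    last sample owns ``min(nominal_dt, video_duration - t_last)`` so a
    trailing gap is not silently attributed to it.  ``nominal_dt`` defaults
    to the median inter-sample interval (for a single-sample recording with
    no nominal rate, the remaining video time).
    """
    n = len(rec)
    if n == 0:
        return np.zeros(0)
    dt = np.diff(rec.t)
    if nominal_dt is None:
        nominal_dt = float(np.median(dt)) if n > 1 else rec.video_duration - rec.t[-1]
    last = min(nominal_dt, rec.video_duration - rec.t[-1])
    return np.append(dt, max(last, 0.0))


def box_at(track: AOITrack, t: float) -> Rect | None:
    """Interpolated bounding box at time ``t``, or None outside the lifetime.

    Corner coordinates are interpolated independently and linearly between
    the bracketing keyframes; the result is exact at keyframes.
    """
    frame = t * track.fps
    frames = np.array([f for f, _ in track.keyframes], dtype=float)
    if frame < frames[0] or frame > frames[-1]:
        return None
    boxes = np.array(
        [[b.x1, b.y1, b.x2, b.y2] for _, b in track.keyframes], dtype=float
    )
    x1, y1, x2, y2 = (np.interp(frame, frames, boxes[:, k]) for k in range(4))
    return Rect(x1, y1, x2, y2)


def boxes_at(track: AOITrack, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`box_at` over a time array.

    Returns ``(present, corners)`` where ``present`` is a boolean mask and
    ``corners`` is an (n, 4) array of x1,y1,x2,y2 (undefined where absent).
    """
    frame = np.asarray(t, dtype=float) * track.fps
    frames = np.array([f for f, _ in track.keyframes], dtype=float)
    boxes = np.array(
        [[b.x1, b.y1, b.x2, b.y2] for _, b in track.keyframes], dtype=float
    )
    present = (frame >= frames[0]) & (frame <= frames[-1])
    corners = np.column_stack(
        [np.interp(frame, frames, boxes[:, k]) for k in range(4)]
    )
    return present, corners


def _tracks_to_frame(tracks: list[AOITrack]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, b in tr.keyframes:
            rows.append(
                (tr.aoi_id, tr.category, tr.object_class, f, b.x1, b.y1, b.x2, b.y2)
            )
    return pd.DataFrame(rows, columns=list(AOI_COLUMNS))


def write_aoi_tracks(tracks: list[AOITrack], path, fps: float = 25.0,
                     margin_deg: float = 2.5) -> None:
    """Write tracks to the versioned AOI CSV dialect."""
    df = _tracks_to_frame(tracks)
    with open(path, "w", newline="") as fh:
        fh.write(f"#format={AOI_FORMAT_VERSION} fps={fps} margin_deg={margin_deg}\n")
        df.to_csv(fh, index=False)


def read_aoi_tracks(path) -> list[AOITrack]:
    """Read the versioned AOI CSV dialect back into tracks.

    The first line carries the format version plus the shared fps and
    margin; an unknown version is refused rather than guessed at.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        body = fh.read()
    if not header.startswith("#format="):
        raise FormatError(f"{path}: missing #format header line")
    fields = dict(kv.split("=", 1) for kv in header.lstrip("#").split())
    if int(fields["format"]) != AOI_FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported format version {fields['format']}")
    fps = float(fields.get("fps", 25.0))
    margin_deg = float(fields.get("margin_deg", 2.5))
    if not body.strip():
        return []
    df = pd.read_csv(io.StringIO(body))
    missing = [c for c in AOI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    tracks = []
    for aoi_id, grp in df.groupby("aoi_id", sort=False):
        grp = grp.sort_values("frame")
        keyframes = tuple(
            (float(r.frame), Rect(r.x1, r.y1, r.x2, r.y2)) for r in grp.itertuples()
        )
        tracks.append(
            AOITrack(
                aoi_id=str(aoi_id),
                category=str(grp["category"].iloc[0]),
                object_class=str(grp["object_class"].iloc[0]),
                keyframes=keyframes,
                fps=fps,
                margin_deg=margin_deg,
            )
        )
    return tracks


def write_metrics(table: pd.DataFrame, path) -> None:
    """Write a metrics table (one row per recording x AOI) to CSV."""
    table.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)
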