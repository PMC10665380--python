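"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

# Property tests must be reproducible run to run.
settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from dynaoi.data_io import (
    GazeRecording,
    ValidityPolicy,
    box_at,
    sample_durations,
    valid_mask,
)
from dynaoi.geometry import ScreenConfig
from dynaoi.metrics import inflate


@pytest.fixture
def screen() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture
def policy() -> ValidityPolicy:
    return ValidityPolicy()


def make_recording(
    t,
    x,
    y,
    confidence=None,
    on_surf=None,
    video_duration=None,
    participant_id="P00",
    session="T1",
    video_id="V1",
) -> GazeRecording:
    """Build a recording from plain sequences with sensible defaults."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    return GazeRecording(
        participant_id=participant_id,
        session=session,
        video_id=video_id,
        video_duration=float(video_duration if video_duration is not None else (t[-1] + 0.01 if n else 0.0)),
        t=t,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        confidence=np.ones(n) if confidence is None else np.asarray(confidence, float),
        on_surf=np.ones(n, bool) if on_surf is None else np.asarray(on_surf, bool),
    )


def pinned_recording(x, y, duration=2.0, rate=100.0, **kw) -> GazeRecording:
    """Gaze held at one point for the whole video."""
    t = np.arange(0.0, duration, 1.0 / rate)
    return make_recording(t, np.full(len(t), float(x)), np.full(len(t), float(y)),
                          video_duration=duration, **kw)


def brute_force_hit_mask(rec, track, cfg, policy) -> np.ndarray:
    """Independent per-sample scan: scalar box lookup, inflation, containment."""
    ok = valid_mask(rec, policy, cfg)
    hits = np.zeros(len(rec), dtype=bool)
    for i in range(len(rec)):
        if not ok[i]:
            continue
        b = box_at(track, rec.t[i])
        if b is None:
            continue
        ib = inflate(b, track.margin_deg, cfg)
        hits[i] = bool(ib.contains(rec.x[i], rec.y[i]))
    return hits


def brute_force_intervals(rec, track, cfg, policy) -> list[tuple[float, float]]:
    """Merge the brute-force hit mask into intervals, clamped to the lifetime."""
    hits = brute_force_hit_mask(rec, track, cfg, policy)
    dur = sample_durations(rec)
    out = []
    i = 0
    n = len(rec)
    while i < n:
        if not hits[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hits[j + 1]:
            j += 1
        start = max(rec.t[i], track.onset)
        end = min(rec.t[j] + dur[j], track.offset)
        if end > start:
            out.append((float(start), float(end)))
        i = j + 1
    return out
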