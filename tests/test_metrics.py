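"""AOI hit/entry/dwell metrics and screen-region dwell ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynaoi.data_io import AOITrack, Rect, ValidityPolicy
from dynaoi.geometry import ScreenConfig, deg_to_px
from dynaoi.metrics import (
    cohort_aoi_stats,
    entry_and_dwell,
    hit_intervals,
    hit_mask,
    inflate,
    region_ratios,
)
from dynaoi.synthetic import SyntheticConfig, make_aoi_set, simulate_cohort

from conftest import brute_force_hit_mask, brute_force_intervals, make_recording, pinned_recording


def static_track(box, t0=0.0, t1=2.0, fps=25.0, margin_deg=2.5, aoi_id="a"):
    return AOITrack(
        aoi_id=aoi_id, category="MUST_BE_SEEN", object_class="car",
        keyframes=((round(t0 * fps), box), (round(t1 * fps), box)),
        fps=fps, margin_deg=margin_deg,
    )


class TestInflate:
    def test_zero_margin_identity(self, screen):
        box = Rect(100, 100, 200, 200)
        assert inflate(box, 0.0, screen) == box

    def test_central_box_offsets_match_geometry(self, screen):
        # 2.5 deg at the screen center is ~105.4 px on each side.
        box = Rect(2879, 599, 2881, 601)
        out = inflate(box, 2.5, screen)
        assert box.x1 - out.x1 == pytest.approx(105.4, abs=0.1)
        assert out.x2 - box.x2 == pytest.approx(105.4, abs=0.1)
        assert out.y2 - box.y2 == pytest.approx(105.4, abs=0.1)

    def test_peripheral_margin_wider_in_local_mode(self, screen):
        box = Rect(100, 550, 200, 650)  # ~47 deg eccentric
        local = inflate(box, 2.5, screen, mode="local")
        central = inflate(box, 2.5, screen, mode="central")
        assert local.x2 - local.x1 > central.x2 - central.x1

    @given(
        x1=st.floats(0, 5000), y1=st.floats(0, 1000),
        w=st.floats(1, 700), h=st.floats(1, 190),
        margin=st.floats(0, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_contains_original(self, x1, y1, w, h, margin):
        screen = ScreenConfig()
        box = Rect(x1, y1, x1 + w, y1 + h)
        out = inflate(box, margin, screen)
        assert out.x1 <= box.x1 and out.y1 <= box.y1
        assert out.x2 >= box.x2 and out.y2 >= box.y2


class TestHitIntervals:
    def test_gaze_pinned_to_aoi_center_covers_lifetime(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.2, t1=1.4)
        rec = pinned_recording(4050, 550, duration=2.0)
        ivs = hit_intervals(rec, track, screen, policy)
        assert len(ivs) == 1
        s, e = ivs[0]
        assert s == pytest.approx(track.onset, abs=0.011)
        assert e == pytest.approx(track.offset, abs=0.011)

    def test_gaze_never_inside_gives_no_intervals(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600))
        rec = pinned_recording(500, 550, duration=2.0)
        assert hit_intervals(rec, track, screen, policy) == []

    def test_planted_visit_length_recovered(self, screen, policy):
        # 0.5 s excursion into the AOI in the middle of its lifetime.
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.0, t1=2.0)
        t = np.arange(0, 2.0, 0.01)
        x = np.where((t >= 0.8) & (t < 1.3), 4050.0, 500.0)
        rec = make_recording(t, x, np.full(len(t), 550.0), video_duration=2.0)
        ivs = hit_intervals(rec, track, screen, policy)
        assert len(ivs) == 1
        assert ivs[0][1] - ivs[0][0] == pytest.approx(0.5, abs=0.011)

    def test_invalid_samples_break_intervals(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.0, t1=2.0)
        t = np.arange(0, 2.0, 0.01)
        conf = np.ones(len(t))
        conf[(t >= 0.5) & (t < 0.7)] = 0.0  # blink mid-visit
        rec = make_recording(t, np.full(len(t), 4050.0), np.full(len(t), 550.0),
                             confidence=conf, video_duration=2.0)
        ivs = hit_intervals(rec, track, screen, policy)
        assert len(ivs) == 2

    def test_matches_brute_force_oracle_on_randomized_inputs(self, screen, policy):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            aois = make_aoi_set(
                3, {"CORE": 0.34, "BAND": 0.33, "PERIPHERY": 0.33}, screen,
                rng, video_duration=6.0,
            )
            cfg = SyntheticConfig(n_participants=2, video_duration=6.0,
                                  sampling_rate=60.0, seed=seed)
            recs, _ = simulate_cohort(aois, cfg, screen)
            for rec in recs:
                for tr in aois:
                    np.testing.assert_array_equal(
                        hit_mask(rec, tr, screen, policy),
                        brute_force_hit_mask(rec, tr, screen, policy),
                    )
                    assert hit_intervals(rec, tr, screen, policy) == pytest.approx(
                        brute_force_intervals(rec, tr, screen, policy)
                    )


class TestEntryAndDwell:
    def test_gaze_inside_at_onset_has_zero_entry(self, screen, policy):
        # Central onset + margins: entry time 0 without any saccade.
        track = static_track(Rect(2850, 570, 2910, 630), t0=0.5, t1=1.5)
        rec = pinned_recording(2880, 600, duration=2.0)
        r = entry_and_dwell(rec, track, screen, policy)
        assert r.viewed
        assert r.entry_time == pytest.approx(0.0, abs=0.011)

    def test_planted_saccade_latency_recovered(self, screen, policy):
        # Saccade lands in the AOI 0.795 s after onset.
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.2, t1=2.0)
        t = np.arange(0, 2.0, 0.01)
        x = np.where(t >= 0.2 + 0.795, 4050.0, 500.0)
        rec = make_recording(t, x, np.full(len(t), 550.0), video_duration=2.0)
        r = entry_and_dwell(rec, track, screen, policy)
        assert r.entry_time == pytest.approx(0.795, abs=0.011)

    def test_no_hits(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600))
        rec = pinned_recording(500, 550, duration=2.0)
        r = entry_and_dwell(rec, track, screen, policy)
        assert not r.viewed and r.entry_time is None and r.dwell_time == 0.0

    def test_dwell_bounded_by_lifetime(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.5, t1=1.0)
        rec = pinned_recording(4050, 550, duration=2.0)
        r = entry_and_dwell(rec, track, screen, policy)
        assert r.dwell_time <= track.offset - track.onset + 1e-9

    def test_margin_monotonicity(self, screen, policy):
        # Growing the margin never decreases dwell or increases entry.
        rng = np.random.default_rng(3)
        t = np.arange(0, 3.0, 0.01)
        x = rng.uniform(3000, 5000, len(t))
        y = rng.uniform(300, 900, len(t))
        rec = make_recording(t, x, y, video_duration=3.0)
        box = Rect(3900, 450, 4150, 700)
        prev_dwell, prev_entry = -1.0, np.inf
        for margin in (0.0, 1.0, 2.5, 5.0):
            track = static_track(box, t0=0.0, t1=3.0, margin_deg=margin)
            r = entry_and_dwell(rec, track, screen, policy)
            assert r.dwell_time >= prev_dwell
            entry = r.entry_time if r.viewed else np.inf
            assert entry <= prev_entry or entry == prev_entry
            prev_dwell, prev_entry = r.dwell_time, entry


class TestCohortStats:
    def test_median_of_viewers(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.0, t1=2.0)
        recs = []
        for latency in (0.1, 0.2, 0.9):
            t = np.arange(0, 2.0, 0.01)
            x = np.where(t >= latency, 4050.0, 500.0)
            recs.append(make_recording(t, x, np.full(len(t), 550.0),
                                       video_duration=2.0))
        n, med = cohort_aoi_stats(recs, track, screen, policy)
        assert n == 3
        assert med == pytest.approx(0.2, abs=0.011)

    def test_nonviewers_excluded_from_count_and_median(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600), t0=0.0, t1=2.0)
        viewers = [pinned_recording(4050, 550, duration=2.0) for _ in range(3)]
        lookers_away = [pinned_recording(500, 550, duration=2.0) for _ in range(17)]
        n, med = cohort_aoi_stats(viewers + lookers_away, track, screen, policy)
        assert n == 3
        assert med is not None

    def test_no_viewers(self, screen, policy):
        track = static_track(Rect(4000, 500, 4100, 600))
        recs = [pinned_recording(500, 550, duration=2.0)]
        assert cohort_aoi_stats(recs, track, screen, policy) == (0, None)

    def test_empty_cohort_rejected(self, screen, policy):
        with pytest.raises(ValueError):
            cohort_aoi_stats([], static_track(Rect(0, 0, 1, 1)), screen, policy)


class TestRegionRatios:
    def test_pinned_center_fills_central_regions(self, screen, policy):
        rec = pinned_recording(2880, 600, duration=2.0)
        rr = region_ratios(rec, screen, policy)
        assert rr.entire_screen == pytest.approx(1.0, abs=1e-9)
        assert rr.central10 == pytest.approx(1.0, abs=1e-9)

    def test_partition_identities(self, screen, policy):
        rng = np.random.default_rng(7)
        t = np.arange(0, 3.0, 0.01)
        rec = make_recording(
            t, rng.uniform(-100, 5860, len(t)), rng.uniform(-50, 1250, len(t)),
            confidence=rng.uniform(0, 1, len(t)), video_duration=3.0,
        )
        rr = region_ratios(rec, screen, policy)
        assert rr.left + rr.right == pytest.approx(rr.entire_screen, abs=1e-9)
        assert rr.top + rr.bottom == pytest.approx(rr.entire_screen, abs=1e-9)
        assert rr.central10 <= rr.central20 <= rr.central30 <= rr.entire_screen

    def test_planted_off_surface_fraction(self, screen, policy):
        # 30% of video time spent off-surface: entire_screen ratio 0.70.
        t = np.arange(0, 2.0, 0.01)
        x = np.where(t < 0.6, -50.0, 2880.0)
        rec = make_recording(t, x, np.full(len(t), 600.0), video_duration=2.0)
        rr = region_ratios(rec, screen, policy)
        assert rr.entire_screen == pytest.approx(0.70, abs=0.011)

    def test_denominator_is_video_length_not_valid_time(self, screen, policy):
        # Half the samples blinked away: every ratio halves.
        t = np.arange(0, 2.0, 0.01)
        conf = np.where(t < 1.0, 0.0, 1.0)
        rec = make_recording(t, np.full(len(t), 2880.0), np.full(len(t), 600.0),
                             confidence=conf, video_duration=2.0)
        rr = region_ratios(rec, screen, policy)
        assert rr.entire_screen == pytest.approx(0.5, abs=0.011)

    def test_zero_duration_rejected(self, screen, policy):
        rec = make_recording([0.0], [2880], [600], video_duration=0.0)
        with pytest.raises(ValueError):
            region_ratios(rec, screen, policy)
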