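# dynaoi

Dynamic area-of-interest (AOI) analysis for wide-field, screen-based eye
tracking.

`dynaoi` is written for researchers who present wide driving-scene videos on
a multi-monitor surface (here: a 5760×1200 px, ~100° field of view viewed
from 65 cm) while recording gaze with a head-mounted, surface-mapped eye
tracker, and who need to turn those recordings into interpretable viewing
metrics for *moving* objects — cyclists, pedestrians, cars, traffic lights —
that appear and disappear over the course of each video. Its immediate use
case is hazard-perception testing of drivers with visual field defects
(e.g. glaucoma), where the question is whether a patient's compensatory eye
movements bring safety-relevant objects into view, and how quickly.

## What it computes

For each dynamic AOI (a frame-indexed bounding box track with a 2.5° angular
margin absorbing tracker inaccuracy) and each recording:

* **AOI hits** — valid gaze samples inside the margin-inflated box while the
  AOI is on screen;
* **entry time** — seconds from AOI onset to the first hit (0 if gaze is
  already inside at onset);
* **dwell time** — total hit time over the AOI's lifetime;
* cohort **viewer counts** and **median entry times** (medians, because
  entry-time distributions are strongly right-skewed).

Per recording it also computes **screen-region dwell ratios**: time in the
central 10°/20°/30° discs (angular diameters), left/right and top/bottom
halves, and the entire screen, each divided by *total video length* — so the
entire-screen ratio doubles as the valid-observation fraction.

Around these metrics sit:

* a **rater panel** module aggregating expert annotations (≥5 of 10 votes
  include an object; exactly 4 goes to panel review; traffic lights are
  always included; Must-Be-Seen vs May-Be-Seen by majority), plus click
  heatmaps and AOI splitting at state changes (light turns green, brake
  lights come on);
* a two-session **selection pipeline** that excludes AOIs that cannot
  measure deliberate gaze: per session an AOI is flagged if (1) fewer than
  10 participants viewed it, (2) its inflated onset box touches the central
  10° disc (hit "for free" by anyone watching the road), or (3) it starts in
  the 10–30° band with a median entry time under 120 ms — below natural
  saccade latency. Only AOIs flagged in **both** sessions are excluded;
* a **synthetic simulator** generating gaze recordings (central baseline
  fixation, lognormal saccade latencies, Poisson blinks, eccentricity-
  consistent angular tracker noise) and AOI tracks with known ground truth,
  so the whole stack is testable without recorded data.

## Worked example

```python
import numpy as np
from dynaoi import (ScreenConfig, ValidityPolicy, SelectionThresholds,
                    SyntheticConfig, make_aoi_set, simulate_cohort,
                    cohort_aoi_stats, region_ratios, onset_zone)

screen = ScreenConfig()                      # 5760x1200 px, 94.34 ppi, 65 cm
print(f"horizontal span: {screen.horizontal_span_deg:.1f} deg")

aois = make_aoi_set(4, {"PERIPHERY": 1.0}, screen, seed=3, video_duration=15.0)
cfg = SyntheticConfig(n_participants=20, video_duration=15.0, seed=3)
recs, truths = simulate_cohort(aois, cfg, screen)

policy = ValidityPolicy()
tr = aois[0]
n_viewed, median_entry = cohort_aoi_stats(recs, tr, screen, policy)
planted = np.median([t.visits[tr.aoi_id].realized_entry
                     for t in truths if t.visits[tr.aoi_id].realized_visit])
print(f"{tr.aoi_id} ({tr.object_class}, {onset_zone(tr, screen, SelectionThresholds())}): "
      f"viewed by {n_viewed}/20, median entry {median_entry:.3f} s "
      f"(planted {planted:.3f} s)")

rr = region_ratios(recs[0], screen, policy)
print(f"P00 region ratios: entire={rr.entire_screen:.3f} central20={rr.central20:.3f} "
      f"left+right={rr.left + rr.right:.3f}")
```

prints

```
horizontal span: 100.1 deg
aoi_000 (police, PERIPHERY): viewed by 16/20, median entry 0.483 s (planted 0.483 s)
P00 region ratios: entire=0.947 central20=0.753 left+right=0.947
```

The span confirms the display geometry (100° after rounding). The peripheral
AOI was viewed by 16 of 20 simulated participants and the measured cohort
median entry time equals the median latency the simulator planted — the
closed loop the test suite relies on. The region ratios show the two
partition identities (left+right equals the entire-screen ratio, which is
below 1 because blinks contribute no valid time).

## Command line

```bash
dynaoi simulate --out-dir sim/ --n-aois 12 --seed 1      # synthetic cohort
dynaoi metrics sim/ sim/aois.csv --out-metrics m.csv --out-regions r.csv
dynaoi select m_T1.csv m_T2.csv --aoi-file sim/aois.csv \
       --out-decisions decisions.csv --out-report report.csv
dynaoi aggregate --votes votes.csv --out-decisions panel.csv
dynaoi heatmap clicks.csv --out grid.txt
```

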