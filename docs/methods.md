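# Methods

## Display model

The three side-by-side monitors are modeled as one coplanar 5760×1200 px
surface at 94.34 ppi, viewed from 65 cm with the eyes on the normal through
the screen center. With these defaults the horizontal span is
2·atan(77.54 cm / 65 cm) = 100.06°, i.e. the nominal 100° field of view, so
no per-monitor angling is modeled. Pixel coordinates follow the image
convention (origin top-left, y down); surface-mapped gaze exports that use
bottom-left normalized coordinates are flipped at ingestion.

All pixel↔angle conversions use the true arctangent on this flat-plane
model — eccentricities reach 50° at the lateral edges, where the small-angle
approximation would err by ~20%. The eccentricity of a point is the angle
between the gaze ray to that point and the ray to the screen center
(`atan(hypot(dx,dy)/d)`), not `hypot(h,v)` of the two signed angles. A
central disc of angular diameter D is therefore an exact pixel circle of
radius `tan(D/2)·d`.

**Diameter convention.** "Central 10°/20°/30°" always denotes the disc's
angular *diameter* (central 10° ⇔ eccentricity ≤ 5°). The convention is
applied uniformly to the region ratios and to the selection-zone
definitions, so the 10–30° band is the annulus between 5° and 15°
eccentricity.

Angular lengths are converted to pixels *radially at the local
eccentricity*: the extent covering eccentricities e..e+a is
`(tan(e+a) − tan(e))·d`. At the center this is the familiar `tan(a)·d`
(2.5° → 105.4 px); at 47° eccentricity the same 2.5° spans more than twice
as many pixels. AOI margins are converted at the box center per frame by
default ("local" mode); a "central-constant" mode reproduces toolkits that
use one global conversion.

## Samples, validity, time

Metrics are sample-based (no fixation/saccade event detection). A sample is
valid iff its confidence ≥ 0.6 (the conventional pupil-confidence cut — the
tracker-specific value is configurable), it is flagged on-surface, and its
point lies within screen bounds. Each sample owns the interval to the next
sample's timestamp; the last sample owns min(nominal interval, remaining
video time). This weighting makes dwell and ratio computations robust to
irregular sampling.

Region dwell ratios divide valid time per region by **total video length**.
Invalid time (blinks, look-aways) counts toward no region, so the
entire-screen ratio equals the valid-observation fraction; left+right and
top+bottom each sum exactly to it (midline ties go to right/bottom, making
the partitions exact).

## AOI metrics

An AOI hit is a valid sample inside the margin-inflated, linearly
interpolated box (closed boundaries — a point on the edge counts, a
deterministic tie rule). Entry time runs from AOI onset (first keyframe
time, frame k ↔ k/fps) to the first hit sample's timestamp, with no
sub-sample interpolation: tracker noise dominates below one sample interval.
Gaze already inside at onset gives entry 0 — precisely the "free hit"
phenomenon the selection pipeline later screens out. Cohort medians are
taken over viewers only; non-viewers have no entry time. The midpoint
convention is used for even counts.

## Rater aggregation

Votes ≥ 5 (of a 10-rater panel) include an object, exactly 4 sends it to
panel review (review outcomes are an *input* — they are never auto-decided),
≤ 3 excludes it, and traffic lights are always included. Category is the
voters' majority; a 5–5 tie resolves to Must-Be-Seen by default — the
conservative choice for a safety test, since a Must-Be-Seen object demands a
driving action — and is configurable. State-change events (light color,
brake lights) split a track into abutting children that share a synthesized
boundary keyframe, so the children tile the parent's lifetime exactly.
Events are snapped to the nearest integer frame to stay on the frame grid.

## Selection pipeline

Per session: c1 — viewed by fewer than `min_viewers` (default 10, an
absolute count; a half-of-cohort mode computes ceil(n/2) per session
instead); c2 — the inflated onset box intersects the central-10° disc
(intersection, not center containment: the exclusion targets footprint
overlap with where everyone already looks); c3 — the onset box intersects
the 10–30° band (but not the core) and the cohort median entry is under
120 ms, the floor of natural saccade latency. An AOI is excluded only when
flagged in both sessions; a session with no data flags nothing. A forced
KEEP/EXCLUDE overrides file carries panel discretion. The per-class report
guarantees before − excluded = remaining, per class and in total.

## Synthetic generator

The simulator emulates what matters to the metrics and deliberately nothing
else:

* baseline gaze at screen center (drivers watch the road ahead), with
  isotropic angular noise of 2.0° RMS (per-axis σ = 2/√2°), inside the
  1.5–2.5° accuracy band of head-mounted surface-mapped tracking; noise is
  added to the gaze angles and projected back to pixels, so its pixel
  footprint grows with eccentricity exactly as real angular error does;
* per planned visit, an instantaneous relocation to the (moving) AOI center
  at onset + latency, held for the planned dwell; latencies are lognormal
  (median 135 ms by default, log-σ 0.35), matching the right-skew of real
  entry times; overlapping visit plans resolve by earliest-onset priority;
* blinks as a Poisson process (15/min, 0.2 s) zeroing confidence;
* viewing probabilities 0.95 (Must-Be-Seen) / 0.80 (May-Be-Seen) per
  participant×AOI.

Defaults describe a 20-participant cohort at 120 Hz. All randomness flows
from one seed; identical seed + config gives identical output.

`make_aoi_set` places onset boxes by rejection sampling and *verifies* each
zone with the selection classifier, so generated CORE/BAND/PERIPHERY labels
are exact by construction. By default, AOIs whose lifetimes overlap keep
disjoint margin-inflated motion hulls — curated stimulus scenes avoid
densely intersecting AOIs for the same reason: a sample inside two AOIs at
once makes entry times uninterpretable. Ground-truth recovery is only
claimed under this condition; with `disjoint=False` cross-AOI hits occur and
entry times for overlapped AOIs are legitimately 0.

What the generator does **not** emulate: saccade kinematics (metrics are
membership-based, so transit time is irrelevant at 120 Hz), smooth pursuit,
head movement, scene content driving attention, or spatially correlated
tracker drift. Passing closed-loop tests therefore show the *analysis* is
correct, not that real gaze behaves like the model.

## Tolerances and test scales

Entry and dwell are quantized to the sample grid, so closed-loop tests use
sample-interval tolerances. With 2.0° noise against a 2.5° margin, the first
on-target sample occasionally lands outside the inflated box, delaying a
measured entry by a sample or two; per-pair tests therefore require ≥90% of
entries within 2 sample intervals, while cohort *medians* (20 participants)
recover the planted median latency within 2 sample intervals in well over
95% of seeded runs for medians of 0.15–0.8 s. The ground-truth reference for
recovery is the median of the latencies actually planted in that cohort (a
20-draw sample median of the lognormal parameter would carry ~70 ms sampling
error at the 0.8 s level, far above measurement resolution — the comparison
would test the sampler, not the metrics).

Test problem sizes (5–20 s videos, 60–120 Hz, 2–20 participants, 3–40 AOIs,
10–50 seeds) were chosen so each suite isolates one effect at a scale where
the expected behavior is hand-checkable; the acceptance script uses the same
scales.

## Degenerate inputs and numerical choices

Rectangles must be non-degenerate (x1<x2, y1<y2); tracks need ≥1 keyframe
and strictly increasing frames; duplicate gaze timestamps keep the last row
(streaming exports supersede); a single-sample recording owns the nominal
interval. Inflation clips to screen bounds extended by one margin, keeping
rectangles finite without clipping reachable off-edge area. `deg_to_px`
refuses angles that (at the local eccentricity) reach 90°, where the flat
plane is never intersected; inflation falls back to the central conversion
for pathological box centers beyond that limit. Empty AOI files round-trip
as a header-only file; unknown format versions are refused rather than
guessed.
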