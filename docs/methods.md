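# Methods

## Pipeline model and assumptions

The pipeline infers feeding behavior purely from the time course of
segmented leaf area. Its core assumptions are:

* **Monotone consumption.** Leaf pixels can only disappear: once a
  pixel is consumed it never becomes leaf again. Leaf shrinkage,
  repositioning or regrowth violate this; slow shrinkage only shows up
  as sub-threshold drift, while a leaf that moves produces false
  feeding events (such assays are meant to be dropped via the
  `exclude_rois` list, mirroring manual QC).
* **Color separability per scan mode.** In reflective scans the leaf
  (and possibly the larva) is the only saturated green object; in
  transmissive scans every opaque object is dark on a white field.
  Segmentation is a plain per-channel range test — no morphology, no
  learning — so any pixel-level ambiguity must be resolved by the
  cumulative rule, not the threshold.
* **One larva per cage, intermittent feeding.** Events are assumed
  disjoint in time within an ROI; simultaneous feeding at two sites
  would be merged into one event.

## Cumulative time-difference masking

mask2(1) = mask1(1); mask2(t+1) = mask1(t+1) ∧ mask2(t). Consequences:

* mask2 foreground sets are nested over time and mask2 ⊆ mask1
  framewise, so the mask2 area series is non-increasing by
  construction.
* A larva-shaped false positive survives exactly as long as the larva
  stays put; each pixel is corrected at the first frame the larva
  vacates it.
* A single background flicker of a noisy pixel deletes it permanently.
  This is inherent to the rule and is deliberately not "fixed": the
  mitigation is a threshold with wide margins (and optionally
  `remove_small_components`, off by default).

## Thresholds

The threshold presets are package defaults chosen on the synthetic
scenes and meant to be overridden per experiment (`threshold:` mapping
in the run config):

* `reflective`: HSV hue ∈ [0.16, 0.50] (green window), saturation
  ≥ 0.20, value ≥ 0.10.
* `transmissive`: HSV value ≤ 0.55.

HSV channels are on the 0–1 scale, RGB on 0–255; a hue range with
lo > hi wraps circularly through 0.

## Event detection and parameters

D(t) = −(S(t+1) − S(t)) / Δt with Δt the frame interval in minutes, so
D is in mm² min⁻¹ for any Δt. An event is a maximal run of points with
D strictly above the threshold (default 0.2 mm² min⁻¹; "exceeds" is
implemented as >, a tie at the threshold is measure-zero in real data).
`min_run` (default 1 point) optionally requires longer runs.

Frame labelling: D at 0-based position i compares frames i+1 and i+2,
and the drop is *observed* at frame i+2. Events are labelled by
observed-drop frames, so `start_frame ≥ 2` always and the pixels lost
during an event are exactly mask2(start_frame−1) ∖ mask2(end_frame) —
the identity the spatial stage relies on.

* area = Σ D over the run × Δt (mm²); duration = run length × Δt;
  rate = area / duration, so rate × duration = area to rounding.
* interval = (start_frame of next − end_frame of current) × Δt. Under
  this end-to-start convention a scripted rest of g minutes is reported
  as g + Δt (the span runs from the last observed drop to the frame
  after the next consumption begins). The offset is constant, identical
  for all events, and cancels in group comparisons; it is asserted in
  the tests rather than hidden.
* Intervals > 100 min (default `max_interval`) are flagged as molting
  pauses and excluded from interval medians only; the flanking events
  keep their duration/area/rate.
* Per-assay summaries are medians over events whose start time lies in
  the first 999 min (`window`); the even-count median is the midpoint.
  An assay with zero qualifying events keeps a row with n_events = 0
  and empty medians rather than disappearing.
* Group comparison: Welch's t-test (scipy `ttest_ind(equal_var=False)`)
  on per-assay medians, with Welch–Satterthwaite df and two-sided p;
  groups are reported as mean ± sample SD (ddof = 1).

## Feeding marks

Mark = mask2(start−1) ∖ mask2(end), computed inside each ROI
independently. Centroid is the unweighted mean of foreground pixel
coordinates ("center of gravity" of a uniform region, no intensity
weighting); mm coordinates originate at the ROI's top-left corner with
x = column, y = row. Consecutive-mark distances are Euclidean in mm.
Overlays use the first mask2 frame as the reference: leaf black,
current mark magenta, earlier marks cyan, background white.

## Synthetic generator

The generator emulates the assay's study conditions:

* **Schedules** (`random_behavior_script` defaults): 8–15 bouts per
  assay, rates 0.3–1.5 mm² min⁻¹, durations 2–10 min, rests 5–60 min,
  on a 1-min frame grid; optionally one long (e.g. 150 min) molting
  pause. These match the observed scale of young-larva feeding on
  Arabidopsis (typical bout ≈ 4–5 min).
* **Series generator**: S(t) = S(0) − cumulative scripted consumption
  + i.i.d. N(0, σ) measurement noise (default σ = 0.02 mm², the
  pixel-counting jitter of a ~0.1 mm/px scan). Initial area default
  400 mm², a mature rosette leaf.
* **Renderer**: an elliptical leaf (default 220×300 px scene at
  254 dpi = 0.1 mm/px); consumption removes leaf pixels in order of
  distance from the event's site (deterministic tie-break by
  (distance, row, col)), giving connected, pixel-quantized marks whose
  areas match the script to < 1 px². The larva is an ellipse moving
  along a scripted path, with a `leaf_like` (uniform green,
  *P. rapae*-style) or `dark_patterned` (banded with black,
  *S. litura*-style) palette; Gaussian sensor noise (default σ = 2 on
  the 8-bit scale) is added per pixel and channel. Both scan modes are
  rendered with mode-appropriate colors.

What the generator does **not** emulate: leaf texture, veins and
trichomes, specular highlights, JPEG artifacts, frass/feces objects,
leaf shrinkage or movement, larva shape change. Passing tests therefore
demonstrate the correctness of the algorithms under the stated
assumptions, not robustness to every real-scan artifact; threshold
presets in particular will need adjustment on real scanners.

## Numerical choices and degenerate inputs

* Areas are exact integer pixel counts scaled by calibration²; no
  smoothing is applied before differencing.
* Detection on an all-rest series returns an empty event list (not an
  error); a series shorter than 2 frames is an error.
* An event whose mark is empty (consumption below one pixel) is kept in
  the events table but omitted from the spatial table.
* Welch comparison requires ≥ 2 assays with defined medians per group.
* The pipeline is deterministic given inputs and config; the only RNG
  in the package is the synthetic generator's seeded one.

## Problem sizes in the test and acceptance suites

Simulation-based checks use 50 series-level assays (~450 frames each)
and rendered stacks of 20–60 frames at 150×200 to 220×300 px — sizes at
which the rendered oracle remains pixel-exact while the whole suite
runs in well under a minute of compute per module.

## Known limitations

* The interval convention's +1-frame offset (above) makes reported
  intervals comparable within and across assays but not identical to
  the "pure rest time"; subtract one frame interval if that quantity is
  needed.
* Filename serial gaps are treated as consecutive frames (a skipped
  scan compresses time); they are logged as warnings.
* Only rectangular ROIs are supported, matching the cage geometry.
* Hue windows are circular but min/max validation applies to all other
  channels; no multi-window (disjoint-range) thresholds.
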