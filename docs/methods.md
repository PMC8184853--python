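# Methods

This note documents the measurement rules, the synthetic-recording
model, the numerical choices, and the known limitations of `pmpkit`.

## Measurement model

A recording is a uniformly sampled whole-body fluorescence series F(t)
(muscle GCaMP, arbitrary units), optionally with the body aspect ratio
AR(t) = length/width and the tracked centroid on the same grid.  The
default grid is 1 Hz (the tracking workflow extracts one frame per
second); 10 Hz is supported and all rules are expressed in seconds, not
samples.

### Event calling

The moving baseline is the **central moving minimum** (CMM): the
minimum of F over a `window_s` = 40 s window centered on each sample,
truncated at the trace edges.  The detection threshold is
multiplicative, `(1 + frac)`·CMM with `frac` = 0.05 by default and
configurable, because the baseline is a positive fluorescence offset;
traces without a positive offset are rejected rather than silently
thresholded.  Events are maximal runs strictly above the threshold
(samples exactly at a level count as below, which makes boundaries
deterministic); runs closer than `min_separation_s` = 2 s are merged.

Two baselines per event are deliberately distinct and both reported:

* `F0_pre` — the minimum of the 10 s preceding the event **maximum**
  (anchoring the window at the maximum is robust to ill-defined run
  starts under noise); it defines the half-max level
  F₀ + 0.5·(F_max − F₀) whose contiguous super-level run containing the
  maximum is the **half-max duration** (the pre-GSB duration metric).
* `F0_peak` — the minimum within the event run; it normalises the
  **amplitude** ΔF/F₀.

Periods are start-to-start intervals of detector runs (run starts, not
half-max crossings).  Events at the trace edge keep truncated-window
flags instead of being dropped.

### Stage segmentation

* **Whole-body vs local events.** An event is a whole-body contraction
  iff AR drops by ≥ `ar_drop_frac` = 3% (relative) within the event run
  against the median AR of the preceding 5 s.  The value is a package
  default (no published number exists); it implements the conservative
  rule that pre-GSB membership requires a confirmed body contraction.
* **Pre-GSB** runs from the first whole-body event to the GSB onset
  (or, without GSB, to the end of the last whole-body event).
* **GSB detection** is algorithmic although the original scoring was
  visual: candidate epochs are sustained runs above a slow baseline
  (window 150 s — longer than any GSB epoch, so the baseline cannot
  climb inside it; threshold 12% above, far below the tetanus
  elevation but far above noise).  An epoch qualifies when its initial
  oscillation-free plateau (the ventral tetanus) lasts 17–70 s
  (± 2.5 s boundary tolerance for run-edge uncertainty at 1 Hz) and is
  followed by ≥ 8 oscillation peaks at a mean frequency within
  0.10–0.45 Hz.  Oscillation peaks are prominence-gated maxima of the
  detrended epoch; the wave burst is the dominant regularly spaced
  cluster, which rejects isolated detrending artifacts at the epoch
  edges.  The reported GSB end is the end of the oscillation burst:
  the anatomical end marker (head waving) is not recoverable from a
  whole-body fluorescence scalar, and no equivalence is claimed.
* **Post-GSB1/2 split.** Qualifying events lie in the central 30–70%
  of the post-GSB span and are longer (run duration) than the medians
  of both flanks; the boundary follows the last member of the
  maximal-duration qualifying chain, ties resolved toward the earlier
  boundary; with no qualifier the span midpoint is used, flagged.
* **PMP endpoints.** The GCaMP-variation and AR-variation endpoints
  are the earliest post-onset times from which the 60 s rolling
  variance of F and AR stays below an epsilon to the end of the trace.
  Epsilons are set per series relative to a robust quiescent floor:
  `factor` = 4 times the 5th percentile of that series' rolling
  variance after onset.  A fixed fraction of the post-onset epoch
  variance (the alternative `epoch_frac` mode) is unusable in general:
  for a staircase-like AR series the epoch variance is dominated by
  the overall larva-to-puparium decline, so any fixed fraction of it
  dwarfs the window variance contributed by late, small AR steps, and
  for F a fixed fraction can fall below the white-noise floor.  The
  noise-floor rule needs only ≥ 5% of the post-onset epoch to be
  quiescent, which the trailing margin guarantees.
* **Pre-PMP onset** is the first time the trailing-60-s speed stays
  below `speed_threshold` = 30 px/window for ≥ 120 s without ever
  exceeding it again before the PMP onset.
* **Pre-GSB class.** An animal's train is `long` iff
  mean(last two) − mean(first two) half-max durations ≥ 5 s
  (configurable), `short` otherwise; fewer than 4 events → unclassified.
* **Tanning** is an annotation (scored by eye in the original
  workflow); the GSB-to-tanning interval is computed from it, never
  inferred from F.

## Synthetic-recording model

The generator emulates the arena recordings, not the animal's
physiology: its purpose is a ground-truthed testbed whose cohort
statistics match the published wild-type medians, so that blind
recovery of those statistics is a meaningful end-to-end check.

**Timeline.** Per animal, stage durations are drawn from log-normal
distributions whose median and log-spread are matched to the published
median and interquartile range: pre-GSB stage 6.1 min (σ = 0.358), GSB
tetanus 25 s (σ = 0.24, truncated to the observed 17–70 s; 11–12 waves
of 4 s put the total GSB median at 71 s), post-GSB 51.3 min
(σ = 0.214), pre-PMP latency 53.9 min (σ = 0.941).  The contraction
count is derived from the drawn stage length at the nominal 33.3 s
period (clipped to 4–16) and the realized period is stage/count, which
keeps periods clear of the contraction support.  The published record
gives no wild-type count or period medians; 11 × 33.3 s reproduces the
6.1 min stage median and is the package's calibration choice.

**Contraction waveform.** Each contraction is an asymmetric composite
of two raised-cosine half-flanks: a fast 3 s rise (the
quasi-synchronous whole-body contraction) and a slow decay of length
2d − 3 s, giving a closed-form noiseless half-max duration of exactly
d under the preceding-10-s baseline rule.  A symmetric bump cannot
represent the duration ramp: with a symmetric raised cosine the 10 s
baseline window saturates the measurable duration at 10·√2 ≈ 14.1 s
and makes wide peaks fragile under noise (maximum-sample drift on a
flat top pulls the baseline window onto the flank).  Pre-GSB durations
ramp linearly; the endpoint-to-endpoint ramp is scaled by
(n−1)/(n−2) so that the *measured* contrast mean(last two) −
mean(first two) equals the configured 10 s.  Amplitudes ramp from 0.25
to 0.80 ΔF/F₀.  Post-GSB1 events are ~2× longer, ~1.5× stronger and
~2× more separated than post-GSB2 events (8 s/0.45/60 s vs
4 s/0.30/30 s), with 1–2 extra-long (16 s) boundary events between the
stages.  GSB is rendered as a sustained pedestal (0.30·F₀) with the
peristaltic waves riding on top, so the tetanus-to-wave transition has
no step.

**Aspect ratio.** AR starts at 3.5 and is a non-increasing staircase:
each pre-GSB whole-body contraction multiplies AR by (1 − 4%) (3.5% in
the null profile) — a fixed relative drop, so the first contraction is
classifiable regardless of count; GSB removes 0.15 across the wave
burst; post-GSB events remove 0.012 at ~90 s intervals until the AR
stabilization time, after which AR is exactly constant.

**Noise.** Additive white Gaussian noise (σ = 1 fluorescence unit on a
baseline of 100) plus a slow sinusoidal drift (amplitude 3, period
30 min) standing in for the position-dependent illumination baseline;
AR noise σ = 0.002.

**Genotype profiles.**  *Wild type*: the full program.  *Pathway
null* (relaxin-pathway loss): no GSB or post-GSB; pre-GSB-like
contractions are shorter (3 s start, 3 s ramp), weaker (0.15–0.28
ΔF/F₀) and more dispersed (45 s period), and absent altogether in
4/21 = 19% of animals (those animals have no events at all); weak
local fluctuations continue for as long as the control program would
have run — implementing the observation that total PMP duration by
GCaMP variation does not differ between mutants and controls — while
the AR freezes 25 min before the fluctuations cease (precocious
sclerotization).  *Rescue*: wild-type program with tanning delayed by
31 min.  Tanning is annotated at a log-normal 30 min (σ = 0.2) after
the program ends, plus the genotype delay.

**Common random numbers.** Every random quantity is drawn from its own
named substream of the per-animal seed, and per-animal seeds depend
only on the cohort seed and animal index — so cohorts of different
genotypes generated from one base seed share their latency and
stage-duration draws.  Genotype contrasts (AR-endpoint advance,
tanning delay) are therefore paired comparisons, mirroring the
within-experiment design of the original study and removing the very
wide latency dispersion from the contrast estimates.

**Locomotion.** A reflected random walk at 5 px/s inside a
200 × 150 px arena, ramping to rest over 120 s before the pre-PMP
onset, with 0.15 px residual centroid jitter (trailing-speed floor
~16 px/min, safely below the 30 px detection threshold).

**Frames.** Single-larva frames are a supersampled (4×) anti-aliased
bright ellipse on a noisy background; frame segmentation cuts midway
between the Otsu class means so the boundary falls at ~50% pixel
coverage, keeping fitted axes unbiased.

### What the generator does not emulate

Real recordings contain photobleaching, position-dependent
multiplicative gain, occlusions and reflections at arena walls,
peristaltic sub-events inside contractions, multi-animal interactions,
and AR series that transiently rebound between contractions.  Passing
recovery tests therefore demonstrates that the pipeline implements the
published measurement rules correctly and recovers known structure
under realistic noise — not that it is robust to every artifact of
real video.

## Cohort statistics and sampling error

Recovery experiments run at the study's scale (50 wild-type animals;
30 per genotype for contrasts).  A 50-draw log-normal cohort median
carries a standard error of ≈ 1.2533·σ/√n on the log scale (≈ 6% for
the pre-GSB stage, ≈ 17% for the latency), so recovered medians
scatter around the generating values by that much; the recovery tests
allow the published interquartile bands plus one such standard error.
Paired contrasts are much tighter because of the common-random-number
design, except the AR-endpoint contrast, where the ~23% of null
animals without a detected program onset (correctly excluded, as they
have no PMP) break pairing for part of the cohort.

## Numerical conventions

0-based sample indexing with half-open runs; strict `>` at thresholds
and levels; event durations are run length × sample period; pixels as
length units throughout kinematics and morphometrics (image-frame
coordinates, x right, y down); mask extents use a +1 px pixel-extent
correction (exact axis-aligned, ≤ 1 px biased when rotated — hence AR
accuracy of ~2% needs masks ≥ 100 px long); degenerate inputs (empty
traces, all-zero tables, zero-width landmarks, non-positive baselines)
raise `ValueError` rather than returning sentinel values; missing
track records are linearly interpolated and flagged, and a track with
more than half its records missing is rejected.

## Known limitations

* GSB end is the end of the oscillation burst, not the head-waving
  mark; absolute GSB durations are comparable within the package but
  not guaranteed to match visually scored ends.
* The binomial phenotype test is one-sided toward excess events (the
  direction of every mutant comparison); sidedness is configurable.
* Whether the published pre-PMP latency was measured to the first
  contraction of any kind or to the pre-GSB onset is not stated; the
  package measures to the detected pre-GSB onset.
* Multi-group ANOVA/Kruskal–Wallis with post-hoc letter displays is out
  of scope; only the two-sample and frequency procedures the pipeline
  needs are implemented.
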