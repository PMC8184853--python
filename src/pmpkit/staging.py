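"""Segmentation of a recording into pupariation motor-program stages.

The pupariation motor program (PMP) runs pre-GSB -> GSB -> post-GSB1 ->
post-GSB2.  Stage boundaries are recovered blind from the fluorescence
trace, the AR series, and (for the pre-PMP locomotor slowdown) the
tracked speed:

* pre-GSB starts at the first detected *whole-body* contraction, i.e.
  the first event whose run is accompanied by a relative AR drop of at
  least ``ar_drop_frac`` (default 3%); fluorescence events without body
  shortening are classified as local and ignored for staging.
* GSB is found algorithmically (the original scoring was visual): a
  sustained supra-baseline epoch whose initial low-oscillation plateau
  (the ventral tetanus) lasts 17-70 s and is immediately followed by a
  burst of at least ``min_waves`` oscillations inside a peristaltic
  frequency band.  The GSB end reported here is the end of the
  oscillation burst (head waving is not recoverable from a whole-body
  fluorescence scalar).
* post-GSB1/post-GSB2 are split after the one-or-two extra-long events
  found in the central portion of the post-GSB span.
* the two PMP endpoints are the times from which the rolling variance
  of the fluorescence (GCaMP-var) and of the AR (AR-var) permanently
  drop to the quiescent noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .trace import FluorescenceTrace
from .trace_metrics import (
    PeakTrain,
    Peak,
    central_moving_minimum,
    detect_peaks_moving_threshold,
)

__all__ = [
    "StageSegmentation",
    "detect_prepmp_onset",
    "classify_contraction",
    "segment_pregsb",
    "detect_gsb",
    "split_postgsb",
    "stabilization_times",
    "classify_pregsb_type",
    "time_to_tanning",
    "segment_trace",
]


@dataclass
class StageSegmentation:
    """Per-animal stage boundaries and flags (times in seconds)."""

    prepmp_start_s: float | None = None
    pregsb_start_s: float | None = None
    pregsb_end_s: float | None = None
    gsb_start_s: float | None = None
    gsb_end_s: float | None = None
    postgsb1_end_s: float | None = None
    pmp_end_gcamp_s: float | None = None
    pmp_end_ar_s: float | None = None
    gsb_performed: bool = False
    pregsb_performed: bool = False
    pregsb_class: str = "none"          # short | long | none
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------


def detect_prepmp_onset(
    speed: np.ndarray,
    time_s: np.ndarray,
    speed_threshold: float = 30.0,
    dwell_s: float = 120.0,
    until_s: float | None = None,
) -> float | None:
    """First time the speed stays below threshold for at least ``dwell_s``
    and never exceeds it again before ``until_s`` (e.g. the PMP onset).

    Samples where the speed is undefined (NaN, the first trailing window)
    are ignored.  Returns None when the condition is never met.
    """
    speed = np.asarray(speed, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    stop = time_s.size if until_s is None else int(np.searchsorted(time_s, until_s))
    valid = np.flatnonzero(np.isfinite(speed[:stop]))
    if valid.size == 0:
        return None
    above = valid[speed[valid] >= speed_threshold]
    if above.size == 0:
        onset_idx = 0
    else:
        onset_idx = int(above[-1]) + 1
    if onset_idx >= stop:
        return None
    if time_s[stop - 1] - time_s[onset_idx] < dwell_s:
        return None
    return float(time_s[onset_idx])


def classify_contraction(
    trace: FluorescenceTrace,
    peak: Peak,
    ar_drop_frac: float = 0.03,
    pre_window_s: float = 5.0,
) -> str:
    """'whole_body' iff the AR drops by >= ``ar_drop_frac`` (relative)
    within the event run compared with the immediately preceding AR."""
    if trace.AR is None:
        raise ValueError("AR series required to classify contractions")
    w = max(1, int(round(pre_window_s * trace.sampling_rate_hz)))
    lo = max(0, peak.start_idx - w)
    if lo == peak.start_idx:
        pre_ar = float(trace.AR[peak.start_idx])
    else:
        pre_ar = float(np.median(trace.AR[lo:peak.start_idx]))
    run_min = float(np.min(trace.AR[peak.start_idx:peak.end_idx]))
    if pre_ar <= 0:
        return "local"
    drop = (pre_ar - run_min) / pre_ar
    return "whole_body" if drop >= ar_drop_frac else "local"


def segment_pregsb(
    train: PeakTrain,
    classes: list[str],
    gsb_start_s: float | None = None,
) -> tuple[float | None, float | None, bool]:
    """Pre-GSB boundaries from a classified event train.

    Start: first whole-body event start.  End: the GSB start when GSB was
    performed, otherwise the end of the last whole-body event (the first
    event after which no further event shortens the body).
    """
    wb = [p for p, c in zip(train.peaks, classes) if c == "whole_body"]
    if gsb_start_s is not None:
        wb = [p for p in wb if p.start_s < gsb_start_s]
    if not wb:
        return None, None, False
    start = wb[0].start_s
    end = gsb_start_s if gsb_start_s is not None else wb[-1].end_s
    return start, end, True


def detect_gsb(
    trace: FluorescenceTrace,
    tetanus_min_s: float = 17.0,
    tetanus_max_s: float = 70.0,
    min_waves: int = 8,
    wave_band_hz: tuple[float, float] = (0.10, 0.45),
    baseline_window_s: float = 150.0,
    frac: float = 0.12,
    merge_gap_s: float = 3.0,
    smooth_s: float = 9.0,
    wave_prominence_frac: float = 0.10,
    boundary_tol_s: float = 2.5,
) -> tuple[float | None, float | None, bool]:
    """Detect the GSB epoch: tetanic plateau then peristaltic burst.

    Candidate epochs are sustained runs above a slow moving baseline
    (window long enough that the baseline cannot climb inside the
    epoch).  An epoch qualifies when its initial oscillation-free
    plateau lasts ``tetanus_min_s``..``tetanus_max_s`` and is followed
    by >= ``min_waves`` oscillation peaks at a mean frequency inside
    ``wave_band_hz``.  Returns (gsb_start, end-of-burst, performed).
    """
    F = trace.F
    rate = trace.sampling_rate_hz
    dt = trace.dt
    cmm = central_moving_minimum(trace, window_s=baseline_window_s)
    thr = (1.0 + frac) * cmm
    mask = F > thr
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(idx[0::2], idx[1::2]))
    gap = max(1, int(round(merge_gap_s * rate)))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_span = tetanus_min_s + min_waves / wave_band_hz[1]
    smooth = max(3, int(round(smooth_s * rate)) | 1)
    for s, e in merged:
        if (e - s) * dt < min_span:
            continue
        seg = F[s:e]
        detr = seg - uniform_filter1d(seg, smooth)
        prom = wave_prominence_frac * max(np.max(seg) - np.min(cmm[s:e]), 1e-9)
        dist = max(1, int(round(0.8 / (wave_band_hz[1] * dt))))
        pk, _ = find_peaks(detr, prominence=prom, distance=dist)
        if pk.size < min_waves:
            continue
        # the wave burst is the dominant regularly spaced cluster;
        # isolated edge/transition artifacts are split off by gap size
        gaps = np.diff(pk)
        med_gap = np.median(gaps)
        cuts = np.flatnonzero(gaps > 2.5 * med_gap)
        clusters = np.split(pk, cuts + 1)
        pk = max(clusters, key=len)
        if pk.size < min_waves:
            continue
        wave_span = (pk[-1] - pk[0]) * dt
        if wave_span <= 0:
            continue
        freq = (pk.size - 1) / wave_span
        if not (wave_band_hz[0] <= freq <= wave_band_hz[1]):
            continue
        half_period = 0.5 / freq
        tetanus_len = pk[0] * dt - half_period
        # the run edge and wave-center estimates carry a few seconds of
        # boundary uncertainty at 1 Hz sampling
        if not (tetanus_min_s - boundary_tol_s
                <= tetanus_len <= tetanus_max_s + boundary_tol_s):
            continue
        gsb_start = float(trace.time_s[s])
        gsb_end = float(trace.time_s[s] + pk[-1] * dt + half_period)
        return gsb_start, min(gsb_end, float(trace.time_s[e - 1] + dt)), True
    return None, None, False


def split_postgsb(
    train: PeakTrain,
    span_start_s: float,
    span_end_s: float,
    central: tuple[float, float] = (0.30, 0.70),
) -> tuple[float | None, list[str]]:
    """Post-GSB1/2 boundary after the extra-long event group.

    Qualifying events lie in the central portion of the post-GSB span
    and have a run duration exceeding the median duration of both the
    preceding and the following events.  The boundary is placed after
    the last member of the maximal-duration qualifying chain (ties
    resolved toward the earlier boundary); with no qualifier, the span
    midpoint is returned, flagged.
    """
    flags: list[str] = []
    peaks = train.peaks
    if len(peaks) < 3:
        return None, ["too_few_postgsb_peaks"]
    lo = span_start_s + central[0] * (span_end_s - span_start_s)
    hi = span_start_s + central[1] * (span_end_s - span_start_s)
    durs = np.array([p.run_duration_s for p in peaks])
    qualify = []
    for i, p in enumerate(peaks):
        if not (lo <= p.start_s <= hi):
            continue
        before, after = durs[:i], durs[i + 1:]
        if before.size == 0 or after.size == 0:
            continue
        if durs[i] > np.median(before) and durs[i] > np.median(after):
            qualify.append(i)
    if not qualify:
        flags.append("midpoint_fallback")
        return 0.5 * (span_start_s + span_end_s), flags
    best = min(qualify, key=lambda i: (-durs[i], i))
    # boundary after the last member of the adjacent qualifying chain
    last = best
    while last + 1 in qualify:
        last += 1
    return peaks[last].end_s, flags


def _rolling_var(x: np.ndarray, w: int) -> np.ndarray:
    m = uniform_filter1d(x, w, mode="nearest")
    m2 = uniform_filter1d(x * x, w, mode="nearest")
    return np.maximum(m2 - m * m, 0.0)


def stabilization_times(
    trace: FluorescenceTrace,
    onset_s: float,
    var_window_s: float = 60.0,
    eps_mode: str = "noise_floor",
    noise_floor_quantile: float = 0.05,
    noise_floor_factor: float = 4.0,
    epoch_frac: float = 0.01,
) -> tuple[float | None, float | None, list[str]]:
    """PMP endpoints: earliest post-onset time from which the rolling
    variance of F (GCaMP-var) and of AR (AR-var) stays below its epsilon
    until the end of the trace.

    With ``eps_mode='noise_floor'`` (default) each epsilon is a multiple
    of a robust quiescent-floor estimate (a low quantile of that
    series' rolling-variance values after onset); ``'epoch_frac'`` uses
    a fraction of the post-onset epoch variance instead.
    """
    if trace.AR is None:
        raise ValueError("AR series required for stabilization endpoints")
    flags: list[str] = []
    w = max(3, int(round(var_window_s * trace.sampling_rate_hz)))
    i0 = trace.index_at(onset_s)
    out = []
    for x in (trace.F, trace.AR):
        seg = x[i0:]
        if seg.size < 2 * w:
            out.append(None)
            flags.append("trace_too_short")
            continue
        rv = _rolling_var(seg, w)
        if eps_mode == "noise_floor":
            eps = noise_floor_factor * float(np.quantile(rv, noise_floor_quantile))
        elif eps_mode == "epoch_frac":
            eps = epoch_frac * float(np.var(seg))
        else:
            raise ValueError(f"unknown eps_mode {eps_mode!r}")
        exceed = np.flatnonzero(rv > eps)
        if exceed.size == 0:
            out.append(float(trace.time_s[i0]))
        elif exceed[-1] >= rv.size - w:
            out.append(None)
            flags.append("never_stabilizes")
        else:
            out.append(float(trace.time_s[i0 + int(exceed[-1]) + 1]))
    return out[0], out[1], flags


def classify_pregsb_type(
    train: PeakTrain,
    ramp_threshold_s: float = 5.0,
) -> str | None:
    """'long' iff the contraction duration ramps up by at least
    ``ramp_threshold_s`` between the first-two and last-two events."""
    if len(train.peaks) < 4:
        return None
    s = train.summary
    diff = s.last_two_duration_mean_s - s.first_two_duration_mean_s
    return "long" if diff >= ramp_threshold_s else "short"


def time_to_tanning(
    gsb_start_s: float | None,
    tanning_s: float | None,
) -> tuple[float | None, list[str]]:
    """Minutes from GSB onset to annotated cuticle tanning.

    The tanning event is an annotation (ground truth or manual label),
    never inferred from the fluorescence.
    """
    if gsb_start_s is None or tanning_s is None:
        return None, ["missing_annotation"]
    minutes = (tanning_s - gsb_start_s) / 60.0
    flags = ["tanning_before_gsb"] if minutes < 0 else []
    return minutes, flags


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class TraceAnalysis:
    """Full blind analysis of one trace."""

    segmentation: StageSegmentation
    train: PeakTrain                  # all detected events
    classes: list[str]                # whole_body/local per event
    pregsb_train: PeakTrain
    postgsb_train: PeakTrain
    tanning_min: float | None = None


def segment_trace(
    trace: FluorescenceTrace,
    speed: np.ndarray | None = None,
    tanning_s: float | None = None,
    *,
    window_s: float = 40.0,
    frac: float = 0.05,
    min_separation_s: float = 2.0,
    ar_drop_frac: float = 0.03,
    speed_threshold: float = 30.0,
    dwell_s: float = 120.0,
    ramp_threshold_s: float = 5.0,
    var_window_s: float = 60.0,
    gsb_kwargs: dict | None = None,
) -> TraceAnalysis:
    """Run the full blind staging of one trace (deterministic)."""
    seg = StageSegmentation()
    train = detect_peaks_moving_threshold(
        trace, window_s=window_s, frac=frac, min_separation_s=min_separation_s)
    gsb_start, gsb_end, performed = detect_gsb(trace, **(gsb_kwargs or {}))
    seg.gsb_start_s, seg.gsb_end_s, seg.gsb_performed = gsb_start, gsb_end, performed

    classes = [classify_contraction(trace, p, ar_drop_frac=ar_drop_frac)
               for p in train.peaks]
    start, end, pregsb_ok = segment_pregsb(train, classes, gsb_start)
    seg.pregsb_start_s, seg.pregsb_end_s, seg.pregsb_performed = start, end, pregsb_ok

    pre_peaks = [p for p, c in zip(train.peaks, classes)
                 if c == "whole_body"
                 and (gsb_start is None or p.start_s < gsb_start)]
    pregsb_train = PeakTrain(pre_peaks, train.sampling_rate_hz)
    cls = classify_pregsb_type(pregsb_train, ramp_threshold_s)
    seg.pregsb_class = cls if cls is not None else "none"
    if pregsb_ok and cls is None:
        seg.flags.append("pregsb_too_short_to_classify")

    if speed is not None:
        seg.prepmp_start_s = detect_prepmp_onset(
            speed, trace.time_s, speed_threshold=speed_threshold,
            dwell_s=dwell_s, until_s=start)
        if seg.prepmp_start_s is None:
            seg.flags.append("no_prepmp_onset")

    onset = start if start is not None else seg.prepmp_start_s
    if onset is not None:
        g_end, a_end, fl = stabilization_times(
            trace, onset, var_window_s=var_window_s)
        seg.pmp_end_gcamp_s, seg.pmp_end_ar_s = g_end, a_end
        seg.flags.extend(fl)
    else:
        seg.flags.append("no_pmp_onset")

    post_peaks = []
    if gsb_end is not None:
        stop = seg.pmp_end_gcamp_s if seg.pmp_end_gcamp_s is not None else np.inf
        post_peaks = [p for p in train.peaks
                      if gsb_end <= p.start_s < stop]
    postgsb_train = PeakTrain(post_peaks, train.sampling_rate_hz)
    if gsb_end is not None and seg.pmp_end_gcamp_s is not None:
        boundary, fl = split_postgsb(
            postgsb_train, gsb_end, seg.pmp_end_gcamp_s)
        seg.postgsb1_end_s = boundary
        seg.flags.extend(fl)

    tan_min, fl = time_to_tanning(gsb_start, tanning_s)
    return TraceAnalysis(
        segmentation=seg,
        train=train,
        classes=classes,
        pregsb_train=pregsb_train,
        postgsb_train=postgsb_train,
        tanning_min=tan_min,
    )
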