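"""Contraction-peak detection and per-event metrics.

Events are called against a moving baseline: the central moving minimum
(CMM) is the minimum fluorescence within a window (default 40 s) centered
on each sample, and the detection threshold is set a fixed fraction
(default 5%) above it.  Four metrics are computed per event:

* duration — for pre-GSB-style events, the time the fluorescence stays
  above 50% of the rise from a local baseline F0 (minimum of the 10 s
  preceding the event maximum) to the event maximum Fmax; for post-GSB
  events the supra-threshold run length is used instead;
* amplitude — ΔF/F0 with ΔF = Fmax − F0, where here F0 is the minimum
  fluorescence within the event run;
* period — start-to-start interval between consecutive event runs.

The two baselines (preceding-window minimum for duration, within-run
minimum for amplitude) are deliberately kept as distinct fields.
Samples exactly at a threshold or half-max level count as below (strict
comparison), which fixes boundary samples deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

from .trace import FluorescenceTrace

__all__ = [
    "Peak",
    "PeakTrain",
    "TrainSummary",
    "central_moving_minimum",
    "detect_peaks_moving_threshold",
    "halfmax_duration",
    "amplitude",
    "periods",
    "summarize_train",
]


@dataclass
class Peak:
    """One detected contraction event (half-open sample run [start, end))."""

    start_idx: int
    max_idx: int
    end_idx: int
    Fmax: float
    F0_pre: float        # minimum of the 10 s preceding the event maximum
    F0_peak: float       # minimum fluorescence within the run
    halfmax_duration_s: float
    amplitude: float     # (Fmax - F0_peak) / F0_peak
    threshold_used: float
    start_s: float
    end_s: float
    max_s: float
    run_duration_s: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.start_idx <= self.max_idx < self.end_idx):
            raise ValueError("require start_idx <= max_idx < end_idx")


@dataclass
class TrainSummary:
    count: int
    duration_mean_s: float | None = None
    duration_median_s: float | None = None
    amplitude_mean: float | None = None
    amplitude_median: float | None = None
    period_mean_s: float | None = None
    period_median_s: float | None = None
    first_two_duration_mean_s: float | None = None
    last_two_duration_mean_s: float | None = None


@dataclass
class PeakTrain:
    """Time-ordered, non-overlapping contraction events from one trace."""

    peaks: list[Peak]
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        for a, b in zip(self.peaks, self.peaks[1:]):
            if a.end_idx > b.start_idx:
                raise ValueError("peak runs must be disjoint and ordered")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def periods_s(self) -> list[float]:
        return periods(self)

    @property
    def summary(self) -> TrainSummary:
        return summarize_train(self)


def central_moving_minimum(
    trace: FluorescenceTrace | np.ndarray,
    window_s: float = 40.0,
    sampling_rate_hz: float | None = None,
) -> np.ndarray:
    """Minimum of ``F`` over a centered window, truncated at the edges.

    The window at sample i covers samples within ``window_s / 2`` seconds
    of i (inclusive); near the trace edges only the available samples are
    used.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if isinstance(trace, FluorescenceTrace):
        F = trace.F
        rate = trace.sampling_rate_hz
    else:
        F = np.asarray(trace, dtype=float)
        if F.size == 0:
            raise ValueError("empty trace")
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for bare arrays")
        rate = sampling_rate_hz
    half = int(round(window_s * rate / 2.0))
    # edge replication leaves the min over the truncated window unchanged
    return minimum_filter1d(F, size=2 * half + 1, mode="nearest")


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True samples."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def detect_peaks_moving_threshold(
    trace: FluorescenceTrace,
    window_s: float = 40.0,
    frac: float = 0.05,
    min_separation_s: float = 2.0,
    pre_window_s: float = 10.0,
) -> PeakTrain:
    """Call contraction events as maximal runs above a moving threshold.

    threshold(t) = (1 + frac) * CMM(t); runs separated by less than
    ``min_separation_s`` are merged.  Each run is annotated with its
    half-max duration, amplitude, and baselines.
    """
    if frac <= 0:
        raise ValueError("frac must be positive")
    cmm = central_moving_minimum(trace, window_s=window_s)
    if np.any(cmm <= 0):
        raise ValueError(
            "non-positive baseline: relative thresholding needs a trace "
            "with a positive fluorescence offset"
        )
    thr = (1.0 + frac) * cmm
    runs = _runs_above(trace.F > thr)
    gap = max(1, int(round(min_separation_s * trace.sampling_rate_hz)))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    peaks = []
    for s, e in merged:
        peaks.append(_annotate_run(trace, s, e, thr, pre_window_s))
    return PeakTrain(peaks=peaks, sampling_rate_hz=trace.sampling_rate_hz)


def _annotate_run(
    trace: FluorescenceTrace,
    start: int,
    end: int,
    thr: np.ndarray,
    pre_window_s: float,
) -> Peak:
    F = trace.F
    seg = F[start:end]
    max_idx = start + int(np.argmax(seg))
    F0_peak = float(np.min(seg))
    Fmax = float(F[max_idx])
    dt = trace.dt
    dur, F0_pre, flags = _halfmax(trace, max_idx, F0_peak, pre_window_s)
    peak = Peak(
        start_idx=start,
        max_idx=max_idx,
        end_idx=end,
        Fmax=Fmax,
        F0_pre=F0_pre,
        F0_peak=F0_peak,
        halfmax_duration_s=dur,
        amplitude=(Fmax - F0_peak) / F0_peak if F0_peak > 0 else np.nan,
        threshold_used=float(thr[max_idx]),
        start_s=float(trace.time_s[start]),
        end_s=float(trace.time_s[start] + (end - start) * dt),
        max_s=float(trace.time_s[max_idx]),
        run_duration_s=(end - start) * dt,
        flags=flags,
    )
    return peak


def _halfmax(
    trace: FluorescenceTrace,
    max_idx: int,
    F0_peak: float,
    pre_window_s: float,
) -> tuple[float, float, tuple[str, ...]]:
    F = trace.F
    rate = trace.sampling_rate_hz
    w = int(round(pre_window_s * rate))
    flags: tuple[str, ...] = ()
    lo = max_idx - w
    if lo < 0:
        lo = 0
        flags += ("truncated_pre_window",)
    if lo == max_idx:  # event at the very first sample
        F0_pre = F0_peak
        flags += ("pre_window_fallback",)
    else:
        F0_pre = float(np.min(F[lo:max_idx]))
    Fmax = float(F[max_idx])
    level = F0_pre + 0.5 * (Fmax - F0_pre)
    # contiguous super-level run containing the maximum (strict >)
    i = max_idx
    while i > 0 and F[i - 1] > level:
        i -= 1
    j = max_idx + 1
    n = F.size
    while j < n and F[j] > level:
        j += 1
    if i == 0 or j == n:
        flags += ("truncated_halfmax_run",)
    return (j - i) / rate, F0_pre, flags


def halfmax_duration(
    trace: FluorescenceTrace,
    peak: Peak,
    pre_window_s: float = 10.0,
) -> float:
    """Half-max event duration in seconds (see module docstring)."""
    dur, _, _ = _halfmax(trace, peak.max_idx, peak.F0_peak, pre_window_s)
    return dur


def amplitude(peak: Peak) -> float:
    """ΔF/F0 with F0 the minimum fluorescence within the event run."""
    if peak.F0_peak <= 0:
        raise ValueError("fluorescence must be positive to normalise ΔF/F0")
    return (peak.Fmax - peak.F0_peak) / peak.F0_peak


def periods(train: PeakTrain) -> list[float]:
    """Start-to-start intervals between consecutive events (seconds)."""
    starts = [p.start_s for p in train.peaks]
    return [b - a for a, b in zip(starts, starts[1:])]


def summarize_train(train: PeakTrain) -> TrainSummary:
    """Count, central tendencies, and first/last-two duration means."""
    n = len(train.peaks)
    if n == 0:
        return TrainSummary(count=0)
    durs = np.array([p.halfmax_duration_s for p in train.peaks])
    amps = np.array([p.amplitude for p in train.peaks])
    out = TrainSummary(
        count=n,
        duration_mean_s=float(np.mean(durs)),
        duration_median_s=float(np.median(durs)),
        amplitude_mean=float(np.mean(amps)),
        amplitude_median=float(np.median(amps)),
    )
    per = periods(train)
    if per:
        out.period_mean_s = float(np.mean(per))
        out.period_median_s = float(np.median(per))
    if n >= 2:
        out.first_two_duration_mean_s = float(np.mean(durs[:2]))
        out.last_two_duration_mean_s = float(np.mean(durs[-2:]))
    return out
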