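import numpy as np
import pytest

from pmpkit.trace import FluorescenceTrace
from pmpkit.trace_metrics import Peak, PeakTrain
from pmpkit.synth import TraceConfig, generate_trace, wild_type_profile


def make_trace(F, rate=1.0, AR=None, baseline=None):
    """Trace from a bare fluorescence array (times 0,1/rate,...)."""
    F = np.asarray(F, dtype=float)
    t = np.arange(F.size) / rate
    return FluorescenceTrace(time_s=t, F=F, AR=AR)


def make_peak(start, end, max_idx=None, dur=None, rate=1.0, **kw):
    """Minimal Peak for staging tests (times derived from indices)."""
    if max_idx is None:
        max_idx = (start + end) // 2
    defaults = dict(
        start_idx=start, max_idx=max_idx, end_idx=end,
        Fmax=kw.pop("Fmax", 150.0), F0_pre=kw.pop("F0_pre", 100.0),
        F0_peak=kw.pop("F0_peak", 100.0),
        halfmax_duration_s=dur if dur is not None else (end - start) / rate,
        amplitude=kw.pop("amplitude", 0.5),
        threshold_used=kw.pop("threshold_used", 105.0),
        start_s=start / rate, end_s=end / rate, max_s=max_idx / rate,
        run_duration_s=(end - start) / rate,
    )
    defaults.update(kw)
    return Peak(**defaults)


def make_train(durations, period=60.0, rate=1.0, start0=0.0):
    """Train of synthetic peaks with given half-max durations."""
    peaks = []
    for k, d in enumerate(durations):
        s = int(round((start0 + k * period) * rate))
        e = s + max(2, int(round(d * rate)))
        peaks.append(make_peak(s, e, max_idx=s, dur=d, rate=rate))
    return PeakTrain(peaks=peaks, sampling_rate_hz=rate)


NOISELESS = TraceConfig(noise_sd=0.0, drift_amplitude=0.0,
                        ar_noise_sd=0.0, rest_jitter_px=0.0)


@pytest.fixture(scope="session")
def wt_noiseless():
    return generate_trace(wild_type_profile(), NOISELESS, seed=11)


@pytest.fixture(scope="session")
def wt_default():
    return generate_trace(wild_type_profile(), TraceConfig(), seed=123)
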