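"""Synthetic pupariation recordings with known ground truth.

The generator emulates single-animal recordings from a pupariation
monitoring arena: a whole-body muscle-GCaMP fluorescence series with a
position-dependent slow baseline drift and white noise, a co-registered
body aspect-ratio (AR) series that steps down at each whole-body
contraction and freezes at sclerotization, and a tracked centroid path
whose trailing-window speed collapses at the pre-PMP locomotor slowdown.

The wild-type timeline is, in order: a wandering locomotor epoch; the
pre-PMP quiescent latency; a pre-GSB train of whole-body contractions
whose half-max duration and amplitude ramp upward; GSB (a tetanic
plateau followed by a burst of peristaltic waves); post-GSB1 (longer,
stronger, more separated contractions); one or two extra-long boundary
contractions; post-GSB2; and quiescence.  Per-animal stage durations are
drawn from log-normal distributions whose median and quartile spread
match the wild-type cohort statistics the pipeline is expected to
recover (pre-GSB 6.1 min, GSB 71 s, post-GSB 51.3 min, pre-PMP latency
53.9 min).

Genotype profiles encode the behavioral contrasts: the pathway-null
profile skips GSB and post-GSB entirely, shows weaker/shorter/more
dispersed pre-GSB-like contractions (absent altogether in a configurable
fraction of animals), keeps GCaMP fluctuations going for as long as the
control motor program would run, and freezes its AR ~25 min before those
fluctuations cease; the rescue profile is wild-type with delayed cuticle
tanning.

Every random quantity is drawn from its own named substream of the
per-animal seed, so cohorts of different genotypes built from the same
base seed share their latency and stage-duration draws (paired designs).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import FluorescenceTrace

__all__ = [
    "GenotypeProfile",
    "TraceConfig",
    "FrameSpec",
    "Contraction",
    "GroundTruth",
    "wild_type_profile",
    "pathway_null_profile",
    "rescue_profile",
    "PROFILES",
    "generate_trace",
    "generate_cohort",
    "generate_frames",
    "generate_counts",
]

# ---------------------------------------------------------------------------
# profiles and configuration


@dataclass(frozen=True)
class GenotypeProfile:
    """Behavioral parameters of one genotype.

    Durations are medians of per-animal log-normal draws; ``*_sigma``
    fields are the log-scale spreads matched to the interquartile range.
    """

    name: str
    # pre-GSB contraction train
    p_no_pregsb: float = 0.0
    pregsb_duration_start_s: float = 4.0
    pregsb_duration_ramp_s: float = 10.0   # mean(last two) - mean(first two)
    pregsb_count_mean: float = 11.0
    pregsb_stage_sigma: float = 0.358      # log-scale spread of stage length
    pregsb_period_s: float = 33.3          # median start-to-start interval
    pregsb_amp_start: float = 0.25         # ΔF/F0 of the first contraction
    pregsb_amp_end: float = 0.80
    pregsb_ar_step_frac: float = 0.04      # relative AR drop per contraction
    # GSB
    has_gsb: bool = True
    gsb_tetanus_s: float = 25.0            # median tetanus plateau
    gsb_tetanus_sigma: float = 0.24
    gsb_wave_count: int = 11               # 11 or 12 waves drawn per animal
    gsb_wave_period_s: float = 4.0
    gsb_total_s: float = 71.0              # nominal tetanus + wave burst
    # post-GSB
    has_postgsb: bool = True
    postgsb_total_min: float = 51.3
    postgsb_total_sigma: float = 0.214
    # pre-PMP
    prepmp_latency_min: float = 53.9
    prepmp_latency_sigma: float = 0.941
    # sclerotization / tanning
    ar_stabilization_offset_min: float = 0.0   # AR freeze relative to GCaMP
    tanning_delay_min: float = 0.0             # extra GSB->tanning delay
    # binary phenotype rates (for count tables)
    p_gsb_failure: float = 1.0 / 376.0
    p_anterior_defect: float = 0.01
    p_death: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.p_no_pregsb, self.p_gsb_failure,
                  self.p_anterior_defect, self.p_death):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in (self.pregsb_duration_start_s, self.pregsb_period_s,
                  self.gsb_tetanus_s, self.postgsb_total_min,
                  self.prepmp_latency_min, self.tanning_delay_min,
                  self.pregsb_duration_ramp_s):
            if v < 0:
                raise ValueError("durations must be nonnegative")
        if self.has_postgsb and not self.has_gsb:
            raise ValueError("post-GSB requires GSB")


def wild_type_profile() -> GenotypeProfile:
    """Control genotype: full four-stage motor program."""
    return GenotypeProfile(name="wild_type")


def pathway_null_profile() -> GenotypeProfile:
    """Relaxin-pathway null: no GSB/post-GSB, weak short pre-GSB
    (absent in 19% of animals), AR freezing ~25 min before GCaMP
    fluctuations cease."""
    return GenotypeProfile(
        name="pathway_null",
        p_no_pregsb=4.0 / 21.0,
        pregsb_duration_start_s=3.0,
        pregsb_duration_ramp_s=3.0,
        pregsb_period_s=45.0,
        pregsb_amp_start=0.15,
        pregsb_amp_end=0.28,
        pregsb_ar_step_frac=0.035,
        has_gsb=False,
        has_postgsb=False,
        ar_stabilization_offset_min=-25.0,
        p_gsb_failure=1.0,
        p_anterior_defect=0.20,
        p_death=0.50,
    )


def rescue_profile() -> GenotypeProfile:
    """Pathway null rescued by late ligand expression: wild-type motor
    program with cuticle tanning delayed by 31 min."""
    return dataclasses.replace(
        wild_type_profile(), name="rescue", tanning_delay_min=31.0
    )


PROFILES = {
    "wild_type": wild_type_profile,
    "pathway_null": pathway_null_profile,
    "rescue": rescue_profile,
}


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition parameters of a synthetic recording."""

    sampling_rate_hz: float = 1.0
    noise_sd: float = 1.0            # fluorescence units
    drift_amplitude: float = 3.0     # slow positional baseline drift
    drift_period_s: float = 1800.0
    baseline_F0: float = 100.0
    peak_shape: str = "raised-cosine"
    duration_s: float | None = None  # None -> auto-sized per animal
    margin_s: float = 720.0          # quiescent tail after the last event
    # AR rendering
    ar_initial: float = 3.5
    ar_noise_sd: float = 0.002
    # locomotion rendering
    wander_speed_px_s: float = 5.0
    slowdown_ramp_s: float = 120.0
    rest_jitter_px: float = 0.15
    arena_px: tuple[float, float] = (200.0, 150.0)
    # contraction waveform
    rise_s: float = 3.0              # fast quasi-synchronous rise

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.peak_shape not in ("raised-cosine", "gaussian"):
            raise ValueError("peak_shape must be raised-cosine or gaussian")


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class Contraction:
    """One simulated contraction event."""

    start_s: float
    max_s: float
    end_s: float
    halfmax_duration_s: float
    amplitude: float            # nominal ΔF/F0 of the rendered bump
    is_whole_body: bool
    stage: str                  # pregsb | postgsb1 | boundary | postgsb2 | local


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated animal."""

    genotype: str
    seed: int
    prepmp_start_s: float
    pregsb_start_s: float | None
    pregsb_end_s: float | None
    gsb_start_s: float | None
    gsb_end_s: float | None
    postgsb1_end_s: float | None
    postgsb2_end_s: float | None
    gcamp_stabilization_s: float
    ar_stabilization_s: float | None
    tanning_s: float
    contractions: list[Contraction] = field(default_factory=list)

    def __post_init__(self) -> None:
        bounds = [
            self.prepmp_start_s, self.pregsb_start_s, self.pregsb_end_s,
            self.gsb_start_s, self.gsb_end_s, self.postgsb1_end_s,
            self.postgsb2_end_s,
        ]
        present = [b for b in bounds if b is not None]
        if any(b > a for a, b in zip(present[1:], present[:-1])):
            raise ValueError("stage boundaries must be nondecreasing")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["contractions"] = [Contraction(**c) for c in d["contractions"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# named substreams

_STREAMS = {
    "prepmp": 1, "latency": 2, "no_pregsb": 3, "count": 4,
    "period_ref": 5, "period_own": 6, "dur_jitter": 7, "amp_jitter": 8,
    "tetanus": 9, "waves": 10, "postgsb": 11, "split": 12, "n_boundary": 13,
    "p1_jitter": 14, "p2_jitter": 15, "tan_gap": 16, "noise": 17,
    "ar_noise": 18, "drift": 19, "walk": 20, "local_jitter": 21,
    "counts": 22, "frames": 23,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def animal_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-animal seed; identical across genotypes so that
    cohorts from one base seed form matched pairs."""
    return (int(cohort_seed) * 1_000_003 + index) % (2**31 - 1)


# ---------------------------------------------------------------------------
# waveforms


def _add_contraction(F: np.ndarray, t: np.ndarray, max_t: float,
                     amp: float, halfmax_s: float, rise_s: float) -> None:
    """Asymmetric contraction bump: raised-cosine rise over ``rise_s``
    then raised-cosine decay over ``2*halfmax_s - rise_s`` so the
    noiseless half-max duration is exactly ``halfmax_s``."""
    fall_s = max(2.0 * halfmax_s - rise_s, rise_s)
    t0, t1 = max_t - rise_s, max_t + fall_s
    i0, i1 = np.searchsorted(t, [t0, t1])
    seg = t[i0:i1]
    up = (seg <= max_t)
    bump = np.empty_like(seg)
    bump[up] = 0.5 * (1.0 - np.cos(np.pi * (seg[up] - t0) / rise_s))
    bump[~up] = 0.5 * (1.0 + np.cos(np.pi * (seg[~up] - max_t) / fall_s))
    F[i0:i1] += amp * bump


def _add_box(F: np.ndarray, t: np.ndarray, t0: float, t1: float,
             amp: float, edge_s: float = 2.0) -> None:
    """Plateau with raised-cosine on/off edges."""
    i0, i1 = np.searchsorted(t, [t0 - edge_s, t1 + edge_s])
    seg = t[i0:i1]
    env = np.ones_like(seg)
    lo = seg < t0
    hi = seg > t1
    env[lo] = 0.5 * (1.0 + np.cos(np.pi * (t0 - seg[lo]) / edge_s))
    env[hi] = 0.5 * (1.0 + np.cos(np.pi * (seg[hi] - t1) / edge_s))
    F[i0:i1] += amp * env


def _add_wave(F: np.ndarray, t: np.ndarray, center: float,
              width: float, amp: float) -> None:
    i0, i1 = np.searchsorted(t, [center - width / 2, center + width / 2])
    seg = t[i0:i1]
    F[i0:i1] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * (seg - center) / width))


# ---------------------------------------------------------------------------
# trace generation


def _reference_timeline(seed: int) -> dict:
    """Control-genotype stage draws shared by every genotype (common
    random numbers; mutants use them to size their fluctuation span)."""
    ref = wild_type_profile()
    prepmp_s = _lognormal(_rng(seed, "prepmp"), 15.0 * 60.0, 0.3)
    latency_s = _lognormal(
        _rng(seed, "latency"), ref.prepmp_latency_min * 60.0,
        ref.prepmp_latency_sigma)
    # the stage length itself is log-normal (median/quartiles matched);
    # the contraction count follows from the nominal period, so the
    # realized period stays clear of the contraction support
    stage_s = _lognormal(_rng(seed, "period_ref"),
                         ref.pregsb_count_mean * ref.pregsb_period_s,
                         ref.pregsb_stage_sigma)
    count = int(np.clip(round(stage_s / ref.pregsb_period_s), 4, 16))
    period_ref = stage_s / count
    tetanus = float(np.clip(
        _lognormal(_rng(seed, "tetanus"), ref.gsb_tetanus_s,
                   ref.gsb_tetanus_sigma), 17.0, 70.0))
    waves = int(ref.gsb_wave_count + _rng(seed, "waves").integers(0, 2))
    postgsb_s = _lognormal(
        _rng(seed, "postgsb"), ref.postgsb_total_min * 60.0,
        ref.postgsb_total_sigma)
    split = float(np.clip(_rng(seed, "split").normal(0.5, 0.03), 0.42, 0.58))
    n_boundary = int(_rng(seed, "n_boundary").integers(1, 3))
    tan_gap_s = _lognormal(_rng(seed, "tan_gap"), 30.0 * 60.0, 0.2)
    gsb_span = tetanus + waves * ref.gsb_wave_period_s
    return dict(
        prepmp_s=prepmp_s, latency_s=latency_s, count=count,
        period_ref=period_ref, tetanus=tetanus, waves=waves,
        postgsb_s=postgsb_s, split=split, n_boundary=n_boundary,
        tan_gap_s=tan_gap_s, gsb_span=gsb_span,
        span_s=count * period_ref + gsb_span + postgsb_s,
    )


def generate_trace(
    profile: GenotypeProfile,
    config: TraceConfig = TraceConfig(),
    seed: int = 0,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one animal; all randomness is fixed by ``seed``."""
    rate = config.sampling_rate_hz
    dt = 1.0 / rate
    F0 = config.baseline_F0
    ref = _reference_timeline(seed)

    prepmp_start = ref["prepmp_s"]
    pregsb_start = prepmp_start + ref["latency_s"]
    count = ref["count"]

    contractions: list[Contraction] = []
    ar_steps: list[tuple[float, float]] = []   # (time, AR decrement)

    no_pregsb = bool(_rng(seed, "no_pregsb").random() < profile.p_no_pregsb)

    # ---- pre-GSB train -----------------------------------------------------
    if profile.has_gsb:
        period_own = ref["period_ref"]
    else:
        period_own = _lognormal(_rng(seed, "period_own"),
                                profile.pregsb_period_s, 0.15)
    d_rng = _rng(seed, "dur_jitter")
    a_rng = _rng(seed, "amp_jitter")
    pregsb_end = None
    first_start = None
    if not no_pregsb:
        n = count
        # endpoint-to-endpoint ramp chosen so that the measured
        # mean(last two) - mean(first two) equals the profile ramp
        ramp = profile.pregsb_duration_ramp_s * ((n - 1) / (n - 2) if n > 2 else 1.0)
        ar_cur = config.ar_initial
        for k in range(n):
            start = pregsb_start + k * period_own
            d = profile.pregsb_duration_start_s + ramp * (k / (n - 1) if n > 1 else 0)
            d = max(config.rise_s + 0.5, d + d_rng.normal(0.0, 0.3))
            frac = k / (n - 1) if n > 1 else 0.0
            amp_rel = (profile.pregsb_amp_start
                       + (profile.pregsb_amp_end - profile.pregsb_amp_start) * frac)
            amp_rel *= max(0.5, 1.0 + a_rng.normal(0.0, 0.05))
            max_t = start + config.rise_s
            fall_s = max(2.0 * d - config.rise_s, config.rise_s)
            contractions.append(Contraction(
                start_s=start, max_s=max_t, end_s=max_t + fall_s,
                halfmax_duration_s=d, amplitude=amp_rel,
                is_whole_body=True, stage="pregsb"))
            dec = profile.pregsb_ar_step_frac * ar_cur
            ar_steps.append((max_t, dec))
            ar_cur -= dec
            if first_start is None:
                first_start = start
        pregsb_end = pregsb_start + n * period_own

    # ---- GSB ---------------------------------------------------------------
    gsb_start = gsb_end = None
    if profile.has_gsb and not no_pregsb:
        gsb_start = pregsb_start + count * ref["period_ref"]
        gsb_end = gsb_start + ref["gsb_span"]

    # ---- GCaMP fluctuation span and sclerotization -------------------------
    gcamp_stab = pregsb_start + ref["span_s"]
    ar_offset_s = profile.ar_stabilization_offset_min * 60.0

    postgsb1_end = postgsb2_end = None
    if profile.has_postgsb and not no_pregsb:
        postgsb_total = ref["postgsb_s"]
        postgsb1_end = gsb_end + ref["split"] * postgsb_total
        postgsb2_end = gsb_end + postgsb_total
        p1_rng = _rng(seed, "p1_jitter")
        p2_rng = _rng(seed, "p2_jitter")
        # post-GSB1: longer, stronger, more separated contractions
        n_b = ref["n_boundary"]
        boundary_zone = 70.0 * n_b
        tpos = gsb_end + 40.0
        i = 0
        while tpos < postgsb1_end - boundary_zone - 20.0:
            d = max(4.0, 8.0 + p1_rng.normal(0.0, 0.6))
            amp = 0.45 * max(0.5, 1.0 + p1_rng.normal(0.0, 0.06))
            max_t = tpos + config.rise_s
            fall = max(2.0 * d - config.rise_s, config.rise_s)
            contractions.append(Contraction(
                start_s=tpos, max_s=max_t, end_s=max_t + fall,
                halfmax_duration_s=d, amplitude=amp,
                is_whole_body=False, stage="postgsb1"))
            if i % 2 == 0:
                ar_steps.append((max_t, 0.012))
            tpos += 60.0 * max(0.5, 1.0 + p1_rng.normal(0.0, 0.08))
            i += 1
        # one or two extra-long boundary contractions
        for j in range(n_b):
            start = postgsb1_end - boundary_zone + j * 70.0
            d = 16.0 + p1_rng.normal(0.0, 0.8)
            max_t = start + config.rise_s
            fall = max(2.0 * d - config.rise_s, config.rise_s)
            contractions.append(Contraction(
                start_s=start, max_s=max_t, end_s=max_t + fall,
                halfmax_duration_s=d, amplitude=0.5,
                is_whole_body=False, stage="boundary"))
            ar_steps.append((max_t, 0.012))
        # the stage boundary is defined by the long-contraction group
        postgsb1_end = contractions[-1].end_s
        # post-GSB2: shorter, weaker, denser
        tpos = postgsb1_end + 20.0
        starts2 = []
        while tpos < postgsb2_end - 15.0:
            starts2.append(tpos)
            tpos += 30.0 * max(0.5, 1.0 + p2_rng.normal(0.0, 0.08))
        for i, start in enumerate(starts2):
            d = max(2.5, 4.0 + p2_rng.normal(0.0, 0.4))
            amp = 0.30 * max(0.5, 1.0 + p2_rng.normal(0.0, 0.06))
            max_t = start + config.rise_s
            fall = max(2.0 * d - config.rise_s, config.rise_s)
            contractions.append(Contraction(
                start_s=start, max_s=max_t, end_s=max_t + fall,
                halfmax_duration_s=d, amplitude=amp,
                is_whole_body=False, stage="postgsb2"))
            if i % 3 == 0 or i == len(starts2) - 1:
                ar_steps.append((max_t, 0.012))
        gcamp_stab = contractions[-1].end_s
        ar_stab = max(t for t, _ in ar_steps) if ar_steps else None
    elif no_pregsb:
        # a fraction of pathway nulls sclerotize without any detectable
        # contraction: quiet trace, no events at all
        gcamp_stab = pregsb_start
        ar_stab = None
    elif not profile.has_gsb:
        # mutant: weak local fluctuations (no body shortening) keep going
        # for as long as the control motor program would have run
        l_rng = _rng(seed, "local_jitter")
        local_start = pregsb_end if pregsb_end is not None else pregsb_start
        ar_stab_target = gcamp_stab + ar_offset_s
        if pregsb_end is not None:
            ar_stab_target = max(ar_stab_target, pregsb_end + 60.0)
        tpos = local_start + 30.0
        locals_: list[Contraction] = []
        while tpos < gcamp_stab - 10.0:
            d = max(2.5, 4.0 + l_rng.normal(0.0, 0.4))
            amp = 0.20 * max(0.5, 1.0 + l_rng.normal(0.0, 0.08))
            max_t = tpos + config.rise_s
            fall = max(2.0 * d - config.rise_s, config.rise_s)
            locals_.append(Contraction(
                start_s=tpos, max_s=max_t, end_s=max_t + fall,
                halfmax_duration_s=d, amplitude=amp,
                is_whole_body=False, stage="local"))
            tpos += 45.0 * max(0.5, 1.0 + l_rng.normal(0.0, 0.1))
        contractions.extend(locals_)
        if locals_:
            gcamp_stab = locals_[-1].end_s
        ar_stab = None
        if locals_ and ar_steps:
            stepping = [c for c in locals_[::2] if c.max_s <= ar_stab_target]
            for c in stepping:
                ar_steps.append((c.max_s, 0.012))
            if stepping:
                ar_stab = stepping[-1].max_s
            else:
                ar_stab = max(t for t, _ in ar_steps)
    else:  # has_gsb but no post-GSB configured
        gcamp_stab = gsb_end if gsb_end is not None else pregsb_start
        ar_stab = max((t for t, _ in ar_steps), default=None)

    tanning = gcamp_stab + ref["tan_gap_s"] + profile.tanning_delay_min * 60.0

    # ---- time base ---------------------------------------------------------
    end_needed = max(gcamp_stab, ar_stab or 0.0) + config.margin_s
    if config.duration_s is not None:
        if config.duration_s < end_needed:
            raise ValueError(
                f"configured stages need {end_needed:.0f} s but duration_s "
                f"is {config.duration_s:.0f} s")
        end_needed = config.duration_s
    t = np.arange(0.0, end_needed, dt)

    # ---- fluorescence ------------------------------------------------------
    F = np.full_like(t, F0)
    for c in contractions:
        if config.peak_shape == "gaussian":
            sd = c.halfmax_duration_s / 2.355
            F += c.amplitude * F0 * np.exp(-0.5 * ((t - c.max_s) / sd) ** 2)
        else:
            _add_contraction(F, t, c.max_s, c.amplitude * F0,
                             c.halfmax_duration_s, config.rise_s)
    if gsb_start is not None:
        # sustained (tetanus-level) pedestal across the whole epoch with
        # the peristaltic waves riding on top: no step at the transition
        _add_box(F, t, gsb_start + 2.0, gsb_end - 1.0, 0.30 * F0)
        wave_zone0 = gsb_start + ref["tetanus"]
        wp = wild_type_profile().gsb_wave_period_s
        for i in range(ref["waves"]):
            frac = i / max(ref["waves"] - 1, 1)
            _add_wave(F, t, wave_zone0 + (i + 0.5) * wp, wp,
                      (0.15 + 0.25 * frac) * F0)

    drift_rng = _rng(seed, "drift")
    phase = drift_rng.uniform(0.0, 2.0 * np.pi)
    F += config.drift_amplitude * np.sin(
        2.0 * np.pi * t / config.drift_period_s + phase)
    if config.noise_sd > 0:
        F += _rng(seed, "noise").normal(0.0, config.noise_sd, t.size)

    # ---- aspect ratio ------------------------------------------------------
    AR = np.full_like(t, config.ar_initial)
    if ar_steps:
        deltas = np.zeros_like(t)
        for ts, d in ar_steps:
            deltas[np.searchsorted(t, ts)] += d
        AR -= np.cumsum(deltas)
    if gsb_start is not None:
        # gradual AR reduction across the peristaltic burst
        zone0, zone1 = gsb_start + ref["tetanus"], gsb_end
        ramp = np.clip((t - zone0) / max(zone1 - zone0, 1.0), 0.0, 1.0)
        AR -= 0.15 * ramp
    if config.ar_noise_sd > 0:
        AR += _rng(seed, "ar_noise").normal(0.0, config.ar_noise_sd, t.size)

    # ---- centroid path -----------------------------------------------------
    x, y = _walk(t, dt, prepmp_start, config, _rng(seed, "walk"))

    trace = FluorescenceTrace(
        time_s=t, F=F, AR=AR, x_px=x, y_px=y,
        meta={"genotype": profile.name, "seed": int(seed)},
    )
    truth = GroundTruth(
        genotype=profile.name,
        seed=int(seed),
        prepmp_start_s=prepmp_start,
        pregsb_start_s=None if no_pregsb else pregsb_start,
        pregsb_end_s=pregsb_end,
        gsb_start_s=gsb_start,
        gsb_end_s=gsb_end,
        postgsb1_end_s=postgsb1_end,
        postgsb2_end_s=postgsb2_end,
        gcamp_stabilization_s=gcamp_stab,
        ar_stabilization_s=ar_stab,
        tanning_s=tanning,
        contractions=sorted(contractions, key=lambda c: c.start_s),
    )
    return trace, truth


def _walk(t, dt, prepmp_start, config: TraceConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Wandering random walk that ramps to rest at the pre-PMP slowdown."""
    w, h = config.arena_px
    ramp0 = prepmp_start - config.slowdown_ramp_s
    speed = np.where(
        t < ramp0, config.wander_speed_px_s,
        config.wander_speed_px_s
        * np.clip((prepmp_start - t) / config.slowdown_ramp_s, 0.0, 1.0))
    heading = np.cumsum(rng.normal(0.0, 0.4, t.size))
    dx = speed * dt * np.cos(heading)
    dy = speed * dt * np.sin(heading)
    x = np.empty_like(t)
    y = np.empty_like(t)
    cx, cy = w / 2.0, h / 2.0
    for i in range(t.size):
        cx += dx[i]
        cy += dy[i]
        # reflect at the arena walls
        if cx < 0:
            cx = -cx
        if cx > w:
            cx = 2 * w - cx
        if cy < 0:
            cy = -cy
        if cy > h:
            cy = 2 * h - cy
        x[i], y[i] = cx, cy
    jitter = config.rest_jitter_px
    if jitter > 0:
        x += rng.normal(0.0, jitter, t.size)
        y += rng.normal(0.0, jitter, t.size)
    return x, y


def generate_cohort(
    profile: GenotypeProfile,
    config: TraceConfig = TraceConfig(),
    n: int = 1,
    seed: int = 0,
) -> list[tuple[FluorescenceTrace, GroundTruth]]:
    """Generate ``n`` independent animals with seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        generate_trace(profile, config, animal_seed(seed, i)) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# frame sequences


@dataclass(frozen=True)
class FrameSpec:
    """Rendering parameters for a synthetic single-larva frame sequence."""

    width_px: int = 160
    height_px: int = 120
    n_frames: int = 60
    axes_px: tuple[float, float] = (30.0, 10.0)   # full major/minor axes
    angle_deg: float = 0.0
    foreground: float = 200.0
    background: float = 30.0
    noise_sd: float = 5.0
    dt_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) <= 0:
            raise ValueError("frame dimensions must be positive")
        if min(self.axes_px) <= 0:
            raise ValueError("blob axes must be positive")


def generate_frames(
    spec: FrameSpec,
    path: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a bright ellipse on a noisy background, one frame per second.

    ``path`` is an (n_frames, 2) array of centroid (x, y) positions; when
    omitted the blob sits at the frame center.  Returns the uint8 frame
    stack and a ground-truth table (t_s, x_px, y_px, ar, brightness).
    """
    n = spec.n_frames
    if path is None:
        path = np.tile([[spec.width_px / 2.0, spec.height_px / 2.0]], (n, 1))
    path = np.asarray(path, dtype=float)
    if path.shape != (n, 2):
        raise ValueError("path must have shape (n_frames, 2)")
    a, b = spec.axes_px[0] / 2.0, spec.axes_px[1] / 2.0
    margin = max(a, b) + 2.0
    if (np.any(path[:, 0] < margin) or np.any(path[:, 0] > spec.width_px - margin)
            or np.any(path[:, 1] < margin) or np.any(path[:, 1] > spec.height_px - margin)):
        raise ValueError("blob leaves the frame")
    rng = _rng(seed, "frames")
    th = np.deg2rad(spec.angle_deg)
    ss = 4  # supersampling factor for clean sub-pixel edges
    grid = (np.arange(0, spec.height_px * ss) + 0.5) / ss - 0.5
    gridx = (np.arange(0, spec.width_px * ss) + 0.5) / ss - 0.5
    yy, xx = np.meshgrid(grid, gridx, indexing="ij")
    frames = np.empty((n, spec.height_px, spec.width_px), dtype=np.uint8)
    rows = []
    for i in range(n):
        cx, cy = path[i]
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        inside = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
        cover = inside.reshape(spec.height_px, ss, spec.width_px, ss
                               ).mean(axis=(1, 3))
        img = spec.background + (spec.foreground - spec.background) * cover
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
        rows.append({
            "t_s": i * spec.dt_s, "x_px": cx, "y_px": cy,
            "ar": a / b, "brightness": spec.foreground,
        })
    return frames, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binary phenotype counts


def generate_counts(
    profile: GenotypeProfile,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli phenotype scores for ``n`` animals of one genotype.

    Returns a table with one row per phenotype: genotype, phenotype,
    events, total, percent (percent rounded to one decimal, as reported).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "counts")
    rows = []
    for phenotype, p in (
        ("gsb_failure", profile.p_gsb_failure),
        ("anterior_retraction", profile.p_anterior_defect),
        ("death", profile.p_death),
    ):
        k = int(rng.binomial(n, p))
        rows.append({
            "genotype": profile.name, "phenotype": phenotype,
            "events": k, "total": n,
            "percent": round(100.0 * k / n, 1),
        })
    return pd.DataFrame(rows)
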