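"""Stage segmentation operations on constructed and synthetic inputs."""

import numpy as np
import pytest

from conftest import make_peak, make_trace, make_train

from pmpkit.staging import (
    classify_contraction,
    classify_pregsb_type,
    detect_gsb,
    detect_prepmp_onset,
    segment_pregsb,
    split_postgsb,
    stabilization_times,
    time_to_tanning,
)
from pmpkit.trace_metrics import detect_peaks_moving_threshold


class TestPrepmpOnset:
    def test_always_quiet_onset_at_start(self):
        t = np.arange(500.0)
        onset = detect_prepmp_onset(np.zeros(500), t)
        assert onset == 0.0

    def test_always_fast_absent(self):
        t = np.arange(500.0)
        assert detect_prepmp_onset(np.full(500, 100.0), t) is None

    def test_last_exceedance_plus_one(self):
        t = np.arange(500.0)
        speed = np.zeros(500)
        speed[:200] = 100.0
        assert detect_prepmp_onset(speed, t) == 200.0

    def test_nan_prefix_ignored(self):
        t = np.arange(500.0)
        speed = np.concatenate([np.full(60, np.nan), np.full(140, 100.0),
                                np.zeros(300)])
        assert detect_prepmp_onset(speed, t) == 200.0

    def test_dwell_not_met_absent(self):
        t = np.arange(100.0)
        speed = np.full(100, 100.0)
        speed[-10:] = 0.0
        assert detect_prepmp_onset(speed, t, dwell_s=120.0) is None


def _trace_with_ar_dip(drop_frac):
    F = np.full(200, 100.0)
    F[100:110] = 150.0
    AR = np.full(200, 3.0)
    AR[103:] = 3.0 * (1 - drop_frac)
    return make_trace(F, AR=AR)


class TestClassifyContraction:
    def test_clear_ar_dip_is_whole_body(self):
        tr = _trace_with_ar_dip(0.10)
        peak = make_peak(100, 110, max_idx=103)
        assert classify_contraction(tr, peak, ar_drop_frac=0.03) == "whole_body"

    def test_flat_ar_is_local(self):
        tr = _trace_with_ar_dip(0.0)
        peak = make_peak(100, 110, max_idx=103)
        assert classify_contraction(tr, peak, ar_drop_frac=0.03) == "local"

    def test_missing_ar_rejected(self):
        tr = make_trace(np.full(200, 100.0))
        with pytest.raises(ValueError, match="AR"):
            classify_contraction(tr, make_peak(100, 110))

    def test_matches_ground_truth_on_synthetic(self, wt_default):
        trace, truth = wt_default
        train = detect_peaks_moving_threshold(trace)
        # match detected events to ground-truth contractions by maximum
        truth_by_time = [(c.max_s, c.is_whole_body) for c in truth.contractions]
        n_checked = 0
        for p in train.peaks:
            hits = [wb for (m, wb) in truth_by_time if abs(m - p.max_s) <= 2.0]
            if not hits:
                continue
            got = classify_contraction(trace, p)
            assert (got == "whole_body") == hits[0]
            n_checked += 1
        assert n_checked >= 20


class TestSegmentPregsb:
    def test_no_whole_body_not_performed(self):
        train = make_train([5.0, 5.0], period=40.0)
        start, end, ok = segment_pregsb(train, ["local", "local"])
        assert not ok and start is None and end is None

    def test_single_event_anchors_both_ends(self):
        train = make_train([5.0], period=40.0, start0=100.0)
        start, end, ok = segment_pregsb(train, ["whole_body"])
        assert ok
        assert start == pytest.approx(100.0)
        assert end == pytest.approx(train.peaks[0].end_s)

    def test_end_is_gsb_start_when_present(self):
        train = make_train([5.0, 5.0, 5.0], period=40.0)
        start, end, ok = segment_pregsb(
            train, ["whole_body"] * 3, gsb_start_s=140.0)
        assert ok and end == pytest.approx(140.0)

    def test_recovers_truth_on_wt(self, wt_default):
        from pmpkit.pipeline import analyze_recording

        trace, truth = wt_default
        seg = analyze_recording(trace, truth).segmentation
        period = (truth.gsb_start_s - truth.pregsb_start_s) / max(
            1, sum(c.stage == "pregsb" for c in truth.contractions))
        assert abs(seg.pregsb_start_s - truth.pregsb_start_s) <= period
        assert abs(seg.pregsb_end_s - truth.gsb_start_s) <= period


class TestDetectGsb:
    def test_contraction_train_without_plateau_rejected(self):
        t = np.arange(1200.0)
        F = np.full(1200, 100.0)
        for c in range(100, 1100, 60):
            m = np.abs(t - c) < 6
            F[m] += 50.0 * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 12))
        _, _, performed = detect_gsb(make_trace(F))
        assert not performed

    def test_flat_trace_rejected(self):
        _, _, performed = detect_gsb(make_trace(np.full(1000, 100.0)))
        assert not performed

    def test_recovers_wt_epoch(self, wt_default):
        trace, truth = wt_default
        s, e, ok = detect_gsb(trace)
        assert ok
        assert s == pytest.approx(truth.gsb_start_s, abs=5.0)
        assert e == pytest.approx(truth.gsb_end_s, abs=5.0)


class TestSplitPostgsb:
    def test_boundary_after_long_event(self):
        train = make_train([5.0, 5.0, 12.0, 4.0, 4.0], period=60.0)
        boundary, flags = split_postgsb(train, 0.0, 300.0)
        assert flags == []
        assert boundary == pytest.approx(train.peaks[2].end_s)

    def test_all_equal_falls_back_to_midpoint(self):
        train = make_train([5.0] * 5, period=60.0)
        boundary, flags = split_postgsb(train, 0.0, 300.0)
        assert "midpoint_fallback" in flags
        assert boundary == pytest.approx(150.0)

    def test_too_few_events_absent(self):
        train = make_train([5.0, 6.0], period=60.0)
        boundary, flags = split_postgsb(train, 0.0, 120.0)
        assert boundary is None and "too_few_postgsb_peaks" in flags

    def test_recovers_encoded_boundary(self, wt_default):
        from pmpkit.pipeline import analyze_recording

        trace, truth = wt_default
        seg = analyze_recording(trace, truth).segmentation
        assert seg.postgsb1_end_s == pytest.approx(truth.postgsb1_end_s, abs=60.0)


class TestStabilization:
    def _two_phase_trace(self, t_star=600, n=1800):
        rng = np.random.default_rng(0)
        F = np.full(n, 100.0)
        t = np.arange(float(n))
        for c in range(60, t_star, 45):
            m = np.abs(t - c) < 5
            F[m] += 40.0 * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 10))
        AR = 3.0 - 0.002 * np.minimum(t, t_star)
        F += rng.normal(0, 0.5, n)
        return make_trace(F, AR=AR), t_star

    def test_constant_after_tstar(self):
        tr, t_star = self._two_phase_trace()
        g, a, flags = stabilization_times(tr, onset_s=0.0)
        assert "never_stabilizes" not in flags
        assert g == pytest.approx(t_star, abs=45.0)
        assert a == pytest.approx(t_star, abs=45.0)

    def test_endpoints_never_precede_onset(self, wt_default):
        trace, truth = wt_default
        g, a, _ = stabilization_times(trace, onset_s=truth.pregsb_start_s)
        assert g >= truth.pregsb_start_s
        assert a >= truth.pregsb_start_s

    def test_recovers_truth_on_wt(self, wt_default):
        trace, truth = wt_default
        g, a, _ = stabilization_times(trace, onset_s=truth.pregsb_start_s)
        assert g == pytest.approx(truth.gcamp_stabilization_s, abs=60.0)
        assert a == pytest.approx(truth.ar_stabilization_s, abs=60.0)

    def test_missing_ar_rejected(self):
        tr = make_trace(np.full(500, 100.0))
        with pytest.raises(ValueError):
            stabilization_times(tr, onset_s=0.0)


class TestPregsbType:
    def test_clear_ramp_is_long(self):
        assert classify_pregsb_type(make_train([5.0, 5.0, 15.0, 16.0])) == "long"

    def test_flat_is_short(self):
        assert classify_pregsb_type(make_train([5.0, 5.0, 5.0, 6.0])) == "short"

    def test_too_few_absent(self):
        assert classify_pregsb_type(make_train([5.0, 15.0])) is None


class TestTimeToTanning:
    def test_simple_interval(self):
        minutes, flags = time_to_tanning(0.0, 1860.0)
        assert minutes == pytest.approx(31.0)
        assert flags == []

    def test_missing_annotation(self):
        minutes, flags = time_to_tanning(100.0, None)
        assert minutes is None and "missing_annotation" in flags

    def test_tanning_before_gsb_flagged(self):
        minutes, flags = time_to_tanning(1000.0, 400.0)
        assert minutes == pytest.approx(-10.0)
        assert "tanning_before_gsb" in flags


class TestSegmentationDeterminism:
    def test_idempotent_on_fixed_trace(self, wt_default):
        from pmpkit.pipeline import analyze_recording

        trace, truth = wt_default
        a = analyze_recording(trace, truth).segmentation
        b = analyze_recording(trace, truth).segmentation
        assert a.to_dict() == b.to_dict()

    def test_wt_boundary_order(self, wt_default):
        from pmpkit.pipeline import analyze_recording

        trace, truth = wt_default
        s = analyze_recording(trace, truth).segmentation
        order = [s.prepmp_start_s, s.pregsb_start_s, s.pregsb_end_s,
                 s.gsb_start_s, s.gsb_end_s, s.postgsb1_end_s,
                 s.pmp_end_gcamp_s]
        assert all(a <= b + 1e-9 for a, b in zip(order, order[1:]))
        assert s.pregsb_end_s == s.gsb_start_s
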