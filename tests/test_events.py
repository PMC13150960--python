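"""Slow-oscillation and spindle detectors against constructed and synthetic signals."""

import numpy as np
import pytest

from patchsleep.containers import ArtifactMask, Hypnogram
from patchsleep.events import (DetectorParams, clean_stage_minutes,
                               detect_slow_oscillations, detect_spindles,
                               so_density, spindle_density)
from patchsleep.synthetic import SO_DURATION_S, StageParams, synthesize_night

FS = 100.0


def _so_wave(amp_ptp, freq=0.75, fs=FS):
    """One biphasic period, negative-then-positive, trough-to-peak amp_ptp."""
    t = np.arange(int(fs / freq)) / fs
    return -(amp_ptp / 2.0) * np.sin(2 * np.pi * freq * t)


def _nrem_setup(n_epochs=20, seed=0, noise=3.0):
    rng = np.random.default_rng(seed)
    n = int(n_epochs * 30 * FS)
    x = rng.normal(0.0, noise, n)
    hyp = Hypnogram(["N2"] * n_epochs)
    mask = ArtifactMask.all_clean(n / FS)
    return x, hyp, mask


class TestSlowOscillations:
    def test_large_injected_wave_detected_among_smaller(self):
        x, hyp, mask = _nrem_setup()
        for k, (t0, amp) in enumerate([(30.0, 150.0), (90.0, 30.0), (150.0, 30.0),
                                       (210.0, 30.0), (270.0, 30.0), (330.0, 30.0)]):
            w = _so_wave(amp)
            j = int(t0 * FS)
            x[j : j + w.size] += w
        res = detect_slow_oscillations(x, FS, hyp, mask)
        hits = [e for e in res.events if abs(e.onset - 30.0) < 0.5]
        assert len(hits) == 1
        assert hits[0].amplitude > res.amplitude_threshold
        assert 0.5 <= hits[0].duration <= 2.0

    def test_waves_below_duration_floor_rejected(self):
        # a 3.33-Hz oscillation: every down-to-down crossing lasts 0.3 s
        n = int(10 * 30 * FS)
        t = np.arange(n) / FS
        x = 100.0 * np.sin(2 * np.pi * (1 / 0.3) * t)
        res = detect_slow_oscillations(x, FS, Hypnogram(["N2"] * 10),
                                       ArtifactMask.all_clean(n / FS))
        # filtfilt boundary transients may ring at the record edges; the
        # steady-state interior must contain no candidate
        interior = [c for c in res.candidates if 10.0 < c.onset < n / FS - 10.0]
        assert interior == []

    def test_flat_nrem_empty(self):
        n = int(10 * 30 * FS)
        res = detect_slow_oscillations(np.zeros(n), FS, Hypnogram(["N3"] * 10),
                                       ArtifactMask.all_clean(n / FS))
        assert res.events == []

    def test_no_nrem_empty_not_error(self):
        n = int(4 * 30 * FS)
        res = detect_slow_oscillations(np.zeros(n), FS, Hypnogram(["W"] * 4),
                                       ArtifactMask.all_clean(n / FS))
        assert res.events == []

    def test_audit_rule_self_consistency(self):
        """Every returned SO satisfies the duration bounds and tops the
        recomputed 75th percentile of the exposed candidate pool."""
        hyp = Hypnogram(["N3"] * 20)
        params = {"N3": StageParams(stage="N3", background_amp=20.0, so_rate=5.0, so_amp=150.0)}
        rec, _ = synthesize_night(hyp, params, fs=FS, seed=3)
        mask = ArtifactMask.all_clean(rec.duration_s)
        res = detect_slow_oscillations(rec.channel("EEG Ch1"), FS, hyp, mask)
        amps = np.array([c.amplitude for c in res.candidates])
        thr = np.percentile(amps, 75.0)
        assert res.amplitude_threshold == pytest.approx(thr)
        assert len(res.events) > 0
        for e in res.events:
            assert 0.5 <= e.duration <= 2.0
            assert e.amplitude > thr
        kept = sum(c.kept for c in res.candidates)
        assert kept == len(res.events)

    def test_events_avoid_artifact_windows(self):
        x, hyp, mask = _nrem_setup(seed=2, noise=5.0)
        w = _so_wave(200.0)
        x[int(62 * FS) : int(62 * FS) + w.size] += w  # inside window 12 (60-65 s)
        mask.flags[12] = True
        res = detect_slow_oscillations(x, FS, hyp, mask)
        for e in res.events:
            assert not (e.onset < 65.0 and e.onset + e.duration > 60.0)

    def test_density_arithmetic(self):
        events = [None] * 30
        assert so_density(events, 60.0) == pytest.approx(0.5)
        assert so_density([], 60.0) == 0.0
        with pytest.raises(ValueError):
            so_density(events, 0.0)

    def test_matched_density_tracks_rate_times_survival(self):
        """Detections matched to injected SOs recover rate x the fraction whose
        amplitude clears the percentile rule (oracle from the audit pool)."""
        hyp = Hypnogram(["N3"] * 40)  # 20 min
        params = {"N3": StageParams(stage="N3", background_amp=20.0, so_rate=0.8, so_amp=150.0)}
        matched, expected = 0.0, 0.0
        for seed in range(5):
            rec, truth = synthesize_night(hyp, params, fs=FS, seed=seed)
            mask = ArtifactMask.all_clean(rec.duration_s)
            res = detect_slow_oscillations(rec.channel("EEG Ch1"), FS, hyp, mask)
            surv = np.mean([a > res.amplitude_threshold for (_, _, a) in truth.so_events])
            expected += 0.8 * surv
            for (t0, d0, _) in truth.so_events:
                if any(e.onset < t0 + d0 and e.onset + e.duration > t0 for e in res.events):
                    matched += 1
        matched_density = matched / (5 * 20.0)
        expected_density = expected / 5
        assert abs(matched_density - expected_density) <= 0.3 * expected_density


class TestSpindles:
    def _night_with_bursts(self, seed=0, amp=36.0, rate=3.0, n_epochs=40):
        sp = {"N2": StageParams(stage="N2", background_amp=12.0,
                                spindle_rate=rate, spindle_amp=amp)}
        hyp = Hypnogram(["N2"] * n_epochs)
        rec, truth = synthesize_night(hyp, sp, fs=FS, seed=seed)
        mask = ArtifactMask.all_clean(rec.duration_s)
        return rec.channel("EEG Ch1"), hyp, mask, truth

    def test_injected_bursts_recovered_with_onset_tolerance(self):
        x, hyp, mask, truth = self._night_with_bursts(seed=11)
        events = detect_spindles(x, FS, hyp, "N2", mask)
        hits = 0
        for (t0, d0, _) in truth.spindle_events:
            if any(abs(e.onset - t0) <= 0.3 or (e.onset < t0 + d0 and e.onset + e.duration > t0)
                   for e in events):
                hits += 1
        assert hits >= 0.9 * len(truth.spindle_events)

    def test_long_burst_not_a_single_event(self):
        rng = np.random.default_rng(5)
        n = int(20 * 30 * FS)
        x = rng.normal(0.0, 12.0, n)
        t = np.arange(int(2.5 * FS)) / FS  # 2.5 s: above the duration ceiling
        x[int(60 * FS) : int(60 * FS) + t.size] += 40.0 * np.sin(2 * np.pi * 13.0 * t)
        events = detect_spindles(x, FS, Hypnogram(["N2"] * 20), "N2",
                                 ArtifactMask.all_clean(n / FS))
        for e in events:
            assert not (abs(e.onset - 60.0) < 0.3 and e.duration > 2.0)

    def test_no_stage_epochs_empty(self):
        n = int(4 * 30 * FS)
        assert detect_spindles(np.zeros(n), FS, Hypnogram(["W"] * 4), "N2",
                               ArtifactMask.all_clean(n / FS)) == []

    def test_amplitude_scaling_invariance(self):
        x, hyp, mask, _ = self._night_with_bursts(seed=21, amp=20.0)
        a = detect_spindles(x, FS, hyp, "N2", mask)
        b = detect_spindles(1e3 * x, FS, hyp, "N2", mask)
        assert [(e.onset, e.duration) for e in a] == [(e.onset, e.duration) for e in b]

    def test_events_respect_artifact_windows(self):
        x, hyp, mask, _ = self._night_with_bursts(seed=31)
        mask.flags[60:66] = True  # exclude 300-330 s
        events = detect_spindles(x, FS, hyp, "N2", mask)
        for e in events:
            assert not (e.onset < 330.0 and e.onset + e.duration > 300.0)

    def test_density_arithmetic(self):
        assert spindle_density([None] * 30, 60.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            spindle_density([], 0.0)


class TestDetectorParams:
    def test_percentile_bounds(self):
        with pytest.raises(ValueError):
            DetectorParams(so_amp_percentile=0.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            DetectorParams(rms_window=-0.3)


def test_clean_stage_minutes_counts_unflagged_stage_samples():
    hyp = Hypnogram(["N2"] * 4 + ["W"] * 2)
    mask = ArtifactMask.all_clean(6 * 30.0)
    mask.flags[0] = True  # 5 s of the first N2 epoch
    minutes = clean_stage_minutes(hyp, ("N2",), mask, FS, int(6 * 30 * FS))
    assert minutes == pytest.approx((4 * 30.0 - 5.0) / 60.0)
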