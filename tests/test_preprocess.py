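"""Filters, resampling, covariance artifact detection and the retention gate."""

import numpy as np
import pytest

from patchsleep import preprocess as pp
from patchsleep.containers import CHANNEL_LABELS, Recording

from conftest import make_recording


def sine_recording(freq, duration_s=60.0, fs=250.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (4, 1)), fs, CHANNEL_LABELS)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = sine_recording(10.0)
        out = pp.bandpass(rec, 0.3, 35.0)
        assert abs(rms(out.samples[0]) - rms(rec.samples[0])) < 0.05 * rms(rec.samples[0])

    def test_stopband_tone_attenuated(self):
        # 10 Hz is >2 octaves above a 0.5-1.5 Hz passband: >=20 dB down
        rec = sine_recording(10.0)
        out = pp.bandpass(rec, 0.5, 1.5)
        assert rms(out.samples[0]) <= 0.1 * rms(rec.samples[0])

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((4, 1000)), 100.0, CHANNEL_LABELS)
        out = pp.bandpass(rec, 0.3, 35.0)
        assert np.allclose(out.samples, 0.0)

    def test_passband_idempotent(self):
        rec = sine_recording(10.0)
        once = pp.bandpass(rec, 0.3, 35.0)
        twice = pp.bandpass(once, 0.3, 35.0)
        assert abs(rms(twice.samples[0]) - rms(once.samples[0])) < 0.01 * rms(once.samples[0])

    @pytest.mark.parametrize("band", [(0.0, 10.0), (10.0, 5.0), (1.0, 200.0)])
    def test_invalid_band_rejected(self, band):
        with pytest.raises(ValueError, match="band"):
            pp.bandpass(make_recording(fs=250.0), *band)


class TestNotch:
    def test_line_tone_attenuated_20db(self):
        rec = sine_recording(60.0)
        out = pp.notch(rec)
        assert rms(out.samples[0]) <= 0.1 * rms(rec.samples[0])

    def test_neighbor_tone_preserved(self):
        rec = sine_recording(10.0)
        out = pp.notch(rec)
        assert abs(rms(out.samples[0]) - rms(rec.samples[0])) < 0.05 * rms(rec.samples[0])

    def test_low_fs_advises_skip(self):
        with pytest.raises(ValueError, match="downsampling"):
            pp.notch(make_recording(fs=100.0))


class TestResample:
    def test_sample_count(self):
        rec = make_recording(duration_s=60.0, fs=250.0)
        out = pp.resample(rec, 100.0)
        assert out.n_samples == 6000
        assert out.fs == 100.0

    def test_tone_power_preserved(self):
        from patchsleep.spectral import band_power, welch_psd

        rec = sine_recording(10.0, duration_s=60.0, fs=250.0)
        out = pp.resample(rec, 100.0)
        p_in = band_power(welch_psd(rec.samples[0], 250.0), 9.0, 11.0)
        p_out = band_power(welch_psd(out.samples[0], 100.0), 9.0, 11.0)
        assert abs(p_out - p_in) < 0.01 * p_in

    def test_identity_and_upsampling_error(self):
        rec = make_recording(fs=100.0)
        assert pp.resample(rec, 100.0) is rec
        with pytest.raises(ValueError, match="upsampling"):
            pp.resample(rec, 200.0)


class TestDetectArtifacts:
    def test_white_noise_rarely_flagged(self):
        for seed in (0, 1, 2):
            rec = make_recording(duration_s=5000.0, fs=20.0, seed=seed)  # 1000 windows
            mask = pp.detect_artifacts(rec)
            assert mask.n_windows == 1000
            assert mask.n_flagged / mask.n_windows < 0.02

    def test_burst_window_flagged(self):
        rec = make_recording(duration_s=300.0, fs=100.0, seed=4)
        rec.samples[:, 5000:5500] *= 100.0  # window 10
        mask = pp.detect_artifacts(rec)
        assert mask.flags[10]

    def test_flatline_window_flagged(self):
        rec = make_recording(duration_s=300.0, fs=100.0, seed=5)
        rec.samples[:, 20000:20500] = 0.0  # window 40
        mask = pp.detect_artifacts(rec)
        assert mask.flags[40]

    def test_constant_recording_no_flags(self):
        rec = Recording(np.ones((4, 2000)), 100.0, CHANNEL_LABELS)
        mask = pp.detect_artifacts(rec)
        assert mask.n_flagged == 0
        assert np.allclose(mask.zscores, 0.0)

    def test_invariant_to_channel_order_and_scaling(self):
        rec = make_recording(duration_s=300.0, fs=100.0, seed=6)
        rec.samples[:, 1000:1500] *= 30.0
        base = pp.detect_artifacts(rec)
        permuted = Recording(rec.samples[::-1].copy(), rec.fs, list(rec.channel_labels)[::-1])
        scaled = rec.copy_with(rec.samples * 1e3)
        assert np.array_equal(pp.detect_artifacts(permuted).flags, base.flags)
        assert np.array_equal(pp.detect_artifacts(scaled).flags, base.flags)

    def test_partial_trailing_window_dropped(self):
        rec = make_recording(duration_s=52.5, fs=100.0)
        mask = pp.detect_artifacts(rec)
        assert mask.n_windows == 10  # 52.5 s -> 10 full 5-s windows

    def test_single_channel_rejected(self):
        rec = make_recording(n_channels=1)
        with pytest.raises(ValueError, match="2 channels"):
            pp.detect_artifacts(rec)


class TestQualityGate:
    def test_long_recording_kept(self):
        rec = make_recording(duration_s=6 * 3600.0, fs=1.0)
        assert pp.quality_gate(rec) == (True, "ok")

    def test_short_without_actigraphy_dropped(self):
        rec = make_recording(duration_s=4 * 3600.0, fs=1.0)
        assert pp.quality_gate(rec) == (False, "short_recording")

    def test_short_with_concordant_actigraphy_kept(self):
        rec = make_recording(duration_s=4 * 3600.0, fs=1.0)
        keep, reason = pp.quality_gate(rec, actigraphy_tst_min=270.0)
        assert keep and reason == "short_but_actigraphy_concordant"

    def test_short_with_discordant_actigraphy_dropped(self):
        rec = make_recording(duration_s=4 * 3600.0, fs=1.0)
        assert pp.quality_gate(rec, actigraphy_tst_min=420.0)[0] is False
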