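"""Filtering, resampling, windowed-covariance artifact detection, quality gate.

Filters are 4th-order Butterworth applied forward-backward (zero phase).
Artifact detection z-scores a single scalar per 5-s window — the log of the
mean absolute pairwise inter-channel covariance — across the whole recording
and flags |z| > 3, which catches both flatlined spans (metric collapses to
log ε) and large broadband bursts (metric inflates).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import ArtifactMask, Recording

#: Floor inside the log of the covariance metric; keeps flatline windows finite.
COV_EPS = 1e-12


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2} Hz"
        )


def _sosfiltfilt(sos: np.ndarray, samples: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, samples, axis=-1)


def bandpass(recording: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel."""
    _check_band(low, high, recording.fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    out = recording.copy_with(_sosfiltfilt(sos, recording.samples))
    out.meta.setdefault("filters", []).append(("bandpass", low, high, order))
    return out


def notch(recording: Recording, band: tuple[float, float] = (59.0, 61.0), order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop for power-line noise (59–61 Hz)."""
    low, high = band
    if recording.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {recording.fs} Hz too low for a {low}-{high} Hz notch; "
            "skip the notch after downsampling below the line frequency"
        )
    sos = sps.butter(order, [low, high], btype="bandstop", fs=recording.fs, output="sos")
    out = recording.copy_with(_sosfiltfilt(sos, recording.samples))
    out.meta.setdefault("filters", []).append(("notch", low, high, order))
    return out


def bandpass_array(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass of a bare signal array (detector building block)."""
    _check_band(low, high, fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def resample(recording: Recording, target_fs: float = 100.0) -> Recording:
    """Polyphase (anti-aliased) downsampling to ``target_fs``."""
    if target_fs > recording.fs:
        raise ValueError(
            f"upsampling requested ({recording.fs} -> {target_fs} Hz); only downsampling is supported"
        )
    if target_fs == recording.fs:
        return recording
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    out_samples = sps.resample_poly(recording.samples, frac.numerator, frac.denominator, axis=-1)
    out = Recording(
        samples=out_samples,
        fs=target_fs,
        channel_labels=tuple(recording.channel_labels),
        start_time=recording.start_time,
        meta=dict(recording.meta),
    )
    out.meta["resampled_from_hz"] = recording.fs
    return out


def detect_artifacts(
    recording: Recording, window: float = 5.0, z_threshold: float = 3.0
) -> ArtifactMask:
    """Flag 5-s windows whose inter-channel covariance metric is a |z| > 3 outlier.

    Per window the metric is ``m = log(ε + mean over channel pairs |cov|)``;
    z-scores are taken across all full windows of the recording. A recording
    whose metric is constant across windows (e.g. exactly repeated content)
    yields z ≡ 0 and no flags. The trailing partial window is dropped.
    """
    if recording.n_channels < 2:
        raise ValueError("artifact detection needs at least 2 channels")
    wlen = int(round(window * recording.fs))
    n_win = recording.n_samples // wlen
    if n_win < 2:
        raise ValueError(
            f"need at least 2 full {window}-s windows, recording has {recording.n_samples} samples"
        )
    x = recording.samples[:, : n_win * wlen].reshape(recording.n_channels, n_win, wlen)
    x = x - x.mean(axis=-1, keepdims=True)
    # (C, C, n_win) pairwise covariances, population normalization
    cov = np.einsum("iwt,jwt->ijw", x, x) / wlen
    iu, ju = np.triu_indices(recording.n_channels, k=1)
    metric = np.log(COV_EPS + np.abs(cov[iu, ju, :]).mean(axis=0))
    sd = metric.std()
    if sd == 0:
        z = np.zeros(n_win)
    else:
        z = (metric - metric.mean()) / sd
    return ArtifactMask(flags=np.abs(z) > z_threshold, zscores=z, window_len=window)


def quality_gate(
    recording: Recording,
    artifact_mask: ArtifactMask | None = None,
    actigraphy_tst_min: float | None = None,
    min_hours: float = 5.0,
) -> tuple[bool, str]:
    """Recording-level retention rule.

    A night is kept if it holds at least ``min_hours`` of recording, or if it
    is shorter but wrist actigraphy concordantly shows total sleep under the
    same bound (the short file then reflects short sleep, not data loss).
    """
    if recording.duration_s >= min_hours * 3600.0:
        return True, "ok"
    if actigraphy_tst_min is not None and actigraphy_tst_min < min_hours * 60.0:
        return True, "short_but_actigraphy_concordant"
    return False, "short_recording"
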