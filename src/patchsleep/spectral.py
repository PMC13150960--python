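"""Welch PSD, band powers, composite NREM delta, multitaper spectrogram, delta SNR.

Band definitions follow standard sleep-EEG conventions: delta 0.5–4 Hz, theta
4–8 Hz, alpha 8–12 Hz, beta 12–30 Hz. Relative power normalizes by the summed
power across these four bands only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .containers import ArtifactMask, Hypnogram, Recording

#: Named band intervals (Hz), ordered, non-overlapping interiors.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass
class Psd:
    freqs: np.ndarray  # Hz
    power: np.ndarray  # µV²/Hz
    window_len: float  # s
    overlap: float  # fraction


@dataclass
class Spectrogram:
    times: np.ndarray  # s, window centers
    freqs: np.ndarray  # Hz
    power: np.ndarray  # time x freq, µV²/Hz
    taper_params: tuple  # (time_halfbandwidth, n_tapers, window_len, step)


def welch_psd(x: np.ndarray, fs: float, window: float = 4.0, overlap: float = 0.5) -> Psd:
    """Welch PSD with Hann-tapered, mean-averaged segments.

    Callers exclude artifact spans by passing only clean (concatenated)
    samples, so excluded data contribute no segments.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window * fs))
    if x.size < nperseg:
        raise ValueError(f"signal of {x.size} samples shorter than one {window}-s window")
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=int(nperseg * overlap), average="mean"
    )
    return Psd(freqs=freqs, power=power, window_len=window, overlap=overlap)


def band_power(psd: Psd, low: float, high: float) -> float:
    """Trapezoid-integrated power over [low, high] Hz."""
    sel = (psd.freqs >= low) & (psd.freqs <= high)
    if sel.sum() < 2:
        raise ValueError(f"PSD grid does not resolve band ({low}, {high}) Hz")
    return float(np.trapezoid(psd.power[sel], psd.freqs[sel]))


def relative_band_power(psd: Psd, bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, float]:
    """Fraction of band power relative to the summed power across ``bands``."""
    absolute = {name: band_power(psd, lo, hi) for name, (lo, hi) in bands.items()}
    total = sum(absolute.values())
    if total <= 0:
        raise ValueError("total band power is zero; relative power undefined")
    return {name: p / total for name, p in absolute.items()}


def composite_nrem_delta(
    rel_delta_n2: float, rel_delta_n3: float, minutes_n2: float, minutes_n3: float
) -> float:
    """Duration-weighted average of N2 and N3 relative delta power."""
    if minutes_n2 < 0 or minutes_n3 < 0:
        raise ValueError("stage minutes must be >= 0")
    total = minutes_n2 + minutes_n3
    if total == 0:
        raise ValueError("no N2 or N3 minutes; composite NREM delta undefined")
    return (rel_delta_n2 * minutes_n2 + rel_delta_n3 * minutes_n3) / total


def multitaper_spectrogram(
    x: np.ndarray,
    fs: float,
    window: float = 6.0,
    step: float = 0.25,
    time_halfbandwidth: float = 3.0,
    n_tapers: int = 5,
) -> Spectrogram:
    """DPSS multitaper spectrogram (averaged eigenspectra) for whole-night QC.

    Defaults (6-s window, NW=3, 5 tapers) give ~1 Hz spectral and sub-second
    temporal resolution, the usual regime for sleep spectrogram review.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window * fs))
    hop = int(round(step * fs))
    if win < 8 or hop < 1 or n_tapers < 1 or time_halfbandwidth <= 0:
        raise ValueError("invalid taper parameters")
    if x.size < win:
        raise ValueError(f"signal shorter than one {window}-s window")
    tapers = dpss(win, time_halfbandwidth, Kmax=n_tapers)  # (K, win)
    n_frames = 1 + (x.size - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]  # (n_frames, win)
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(frames[:, None, :] * tapers[None, :, :], axis=-1)
    # average eigenspectra; scale to a density (µV²/Hz)
    power = (np.abs(spec) ** 2).mean(axis=1) / (fs * (tapers**2).sum(axis=1).mean())
    freqs = np.fft.rfftfreq(win, d=1 / fs)
    times = (idx[:, 0] + win / 2) / fs
    # NaN frames that touch NaN samples (excluded spans stay visibly blank)
    bad = ~np.isfinite(frames).all(axis=1)
    power[bad] = np.nan
    return Spectrogram(
        times=times,
        freqs=freqs,
        power=power,
        taper_params=(time_halfbandwidth, n_tapers, window, step),
    )


def _epoch_delta_powers(
    x: np.ndarray,
    fs: float,
    epochs: np.ndarray,
    clean_mask: np.ndarray,
    epoch_len: float,
    min_clean_fraction: float = 0.5,
) -> list[float]:
    """Delta band power per epoch, using only artifact-free samples."""
    spe = int(round(epoch_len * fs))
    powers = []
    for i in epochs:
        seg = x[i * spe : (i + 1) * spe]
        keep = clean_mask[i * spe : (i + 1) * spe]
        if keep.size == 0 or keep.mean() < min_clean_fraction:
            continue
        seg = seg[keep[: seg.size]]
        if seg.size < int(4.0 * fs):
            continue
        psd = welch_psd(seg, fs)
        powers.append(band_power(psd, *BANDS["delta"]))
    return powers


def compute_snr_db(
    recording: Recording,
    hypnogram: Hypnogram,
    artifact_mask: ArtifactMask,
    channel: str = "EEG Ch1",
) -> float:
    """Delta-band SNR: sleep after onset vs. wake before onset, in dB.

    Sleep onset is the first epoch scored other than W. The numerator is the
    mean delta power over artifact-free sleep epochs after onset; the
    denominator the mean over artifact-free pre-onset wake epochs.
    """
    x = recording.channel(channel)
    stages = hypnogram.stage_array()
    sleep_idx = np.flatnonzero(~np.isin(stages, ["W", "UNSCORED"]))
    if sleep_idx.size == 0:
        raise ValueError("no sleep epochs; SNR undefined")
    onset = int(sleep_idx[0])
    pre_wake = np.flatnonzero(stages[:onset] == "W")
    if pre_wake.size == 0:
        raise ValueError("no pre-onset wake epochs; SNR undefined")
    clean = artifact_mask.clean_sample_mask(recording.fs, recording.n_samples)
    wake_p = _epoch_delta_powers(x, recording.fs, pre_wake, clean, hypnogram.epoch_len)
    sleep_p = _epoch_delta_powers(x, recording.fs, sleep_idx, clean, hypnogram.epoch_len)
    if not wake_p or not sleep_p:
        raise ValueError("all candidate epochs excluded by the artifact mask; SNR undefined")
    return float(10.0 * np.log10(np.mean(sleep_p) / np.mean(wake_p)))
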