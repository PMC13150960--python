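"""Sleep-stage provision: hypnogram ingestion and a naive rule-based stager.

The production staging path ingests externally produced hypnograms (the study
used a pre-trained automated classifier, which this package deliberately does
not re-implement — its value is learned weights, not an algorithm). For
synthetic end-to-end tests a clearly-labeled naive stager is provided: a
per-epoch decision list over relative band powers, spindle-band RMS bursts and
EOG deflections. It is a test double, not a validated classifier.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import Hypnogram, Recording
from .preprocess import bandpass_array
from .spectral import BANDS, relative_band_power, welch_psd


def ingest_hypnogram(hypnogram: Hypnogram, recording: Recording) -> Hypnogram:
    """Align an external hypnogram with a recording.

    A hypnogram one epoch short is padded with UNSCORED; one epoch long is
    truncated with a warning; larger mismatches are alignment errors.
    """
    expected = int(recording.duration_s // hypnogram.epoch_len)
    have = hypnogram.n_epochs
    if abs(have - expected) > 1:
        raise ValueError(
            f"hypnogram has {have} epochs but the recording spans {expected}; "
            "misalignment exceeds one epoch"
        )
    if have == expected:
        return hypnogram
    if have < expected:
        return Hypnogram(stages=hypnogram.stages + ["UNSCORED"] * (expected - have))
    warnings.warn(
        f"hypnogram has {have - expected} surplus trailing epoch(s); truncating",
        stacklevel=2,
    )
    return Hypnogram(stages=hypnogram.stages[:expected])


def naive_stage(
    eeg: np.ndarray,
    eog_bipolar: np.ndarray,
    fs: float,
    epoch_len: float = 30.0,
    delta_n3: float = 0.60,
    sigma_burst_factor: float = 2.45,
    delta_n2_min: float = 0.35,
    eog_burst_factor: float = 2.5,
    delta_rem_max: float = 0.62,
    alpha_w: float = 0.22,
) -> Hypnogram:
    """Rule-based staging for synthetic end-to-end tests.

    Per 30-s epoch, in order: relative delta above ``delta_n3`` → N3; a
    sustained spindle-band RMS burst (three consecutive 0.3-s windows whose
    level exceeds ``sigma_burst_factor`` × the epoch's median RMS, with delta
    at least ``delta_n2_min`` to screen out broadband movement) → N2; large
    bipolar-EOG deflections with low delta → REM; a high alpha fraction → W;
    otherwise N1. An epoch with zero power falls back to W. Thresholds were
    tuned on held-out generator seeds.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.asarray(eog_bipolar, dtype=float)
    if eeg.shape != eog.shape:
        raise ValueError("EEG and bipolar EOG must have equal length")
    spe = int(round(epoch_len * fs))
    n_ep = eeg.size // spe
    if n_ep < 1:
        raise ValueError("need at least one full epoch")

    # sigma-band RMS series (0.3-s windows, 0.1-s steps), per-epoch contrast:
    # the strongest 0.3-s-sustained level relative to the epoch's median RMS
    sigma = bandpass_array(eeg, fs, 12.0, 16.0)
    win = int(round(0.3 * fs))
    hop = int(round(0.1 * fs))
    cs2 = np.concatenate([[0.0], np.cumsum(sigma**2)])
    burst_epoch = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        starts = np.arange(i * spe, (i + 1) * spe - win + 1, hop)
        rms = np.sqrt((cs2[starts + win] - cs2[starts]) / win)
        med = np.median(rms)
        if med <= 0 or rms.size < 3:
            continue
        sustained = np.min(np.lib.stride_tricks.sliding_window_view(rms, 3), axis=1)
        burst_epoch[i] = sustained.max() / med > sigma_burst_factor

    rel = np.full((n_ep, 2), np.nan)  # delta, alpha fractions
    eog_peak = np.zeros(n_ep)
    for i in range(n_ep):
        seg = eeg[i * spe : (i + 1) * spe]
        if np.ptp(seg) > 0:
            try:
                rb = relative_band_power(welch_psd(seg, fs), BANDS)
                rel[i] = (rb["delta"], rb["alpha"])
            except ValueError:
                pass
        eog_peak[i] = np.abs(eog[i * spe : (i + 1) * spe]).max()

    med = np.median(eog_peak)
    eog_ref = med if med > 0 else np.inf

    stages = []
    for i in range(n_ep):
        delta, alpha = rel[i]
        if not np.isfinite(delta):
            stages.append("W")  # zero/degenerate signal: documented fallback
        elif delta > delta_n3:
            stages.append("N3")
        elif burst_epoch[i] and delta >= delta_n2_min:
            stages.append("N2")
        elif eog_peak[i] > eog_burst_factor * eog_ref and delta <= delta_rem_max:
            stages.append("REM")
        elif alpha > alpha_w:
            stages.append("W")
        else:
            stages.append("N1")
    return Hypnogram(stages=stages)


def stager_input_from_recording(recording: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Staging channels: EEG Ch1 filtered 0.1–40 Hz and bipolar EOG Ch2 − EOG Ch1."""
    eeg = bandpass_array(recording.channel("EEG Ch1"), recording.fs, 0.1,
                         min(40.0, recording.fs / 2 - 1.0))
    eog = recording.channel("EOG Ch2") - recording.channel("EOG Ch1")
    return eeg, eog
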