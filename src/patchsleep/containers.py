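"""Core in-memory containers shared across the pipeline.

All signals are stored in microvolts (µV), already referenced to the nose
electrode, as a channels x samples matrix. Sleep stages follow AASM labels
in 30-second epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np

#: Valid hypnogram tokens.
STAGES = ("W", "N1", "N2", "N3", "REM", "UNSCORED")
#: Stages counted as sleep.
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
#: Non-REM sleep stages.
NREM_STAGES = ("N1", "N2", "N3")

#: Canonical channel roles of the forehead patch (2 EEG, 2 EOG, nose reference
#: subtracted at acquisition time).
CHANNEL_LABELS = ("EEG Ch1", "EEG Ch2", "EOG Ch1", "EOG Ch2")

EPOCH_LEN_S = 30.0


@dataclass
class Recording:
    """A multi-channel time series in µV.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in µV, referenced to the nose electrode.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique channel names, ordered as the rows of ``samples``.
    start_time : datetime
        Recording start (defaults to a fixed epoch for reproducibility).
    meta : dict
        Free-form provenance (gap reports, filter history, ...).
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str] = CHANNEL_LABELS
    start_time: datetime = field(default_factory=lambda: datetime(2024, 1, 1, 22, 0, 0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label."""
        try:
            idx = list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not present; have {list(self.channel_labels)}"
            ) from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(
            samples=samples,
            fs=self.fs,
            channel_labels=tuple(self.channel_labels),
            start_time=self.start_time,
            meta=dict(self.meta),
        )


@dataclass
class Hypnogram:
    """Sleep-stage labels, one per 30-s epoch."""

    stages: list[str]
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = list(self.stages)
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stage labels: {bad}; allowed: {STAGES}")
        if self.epoch_len != EPOCH_LEN_S:
            raise ValueError(f"epoch_len must be {EPOCH_LEN_S} s, got {self.epoch_len}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def epochs_of(self, *stages: str) -> np.ndarray:
        """Indices of epochs whose label is in ``stages``."""
        arr = self.stage_array()
        return np.flatnonzero(np.isin(arr, stages))

    def minutes_of(self, *stages: str) -> float:
        return len(self.epochs_of(*stages)) * self.epoch_len / 60.0

    def sample_mask(self, fs: float, n_samples: int, stages: Sequence[str]) -> np.ndarray:
        """Boolean per-sample mask, True where the sample lies in one of ``stages``."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(self.epoch_len * fs))
        for i in self.epochs_of(*stages):
            mask[i * spe : min((i + 1) * spe, n_samples)] = True
        return mask


@dataclass
class ArtifactMask:
    """Per-5-s-window artifact flags derived from inter-channel covariance z-scores.

    A flagged window is excluded from every downstream analysis. The trailing
    partial window (shorter than ``window_len``) carries no flag and is also
    excluded from analysis.
    """

    flags: np.ndarray
    zscores: np.ndarray
    window_len: float = 5.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.zscores = np.asarray(self.zscores, dtype=float)
        if self.flags.shape != self.zscores.shape:
            raise ValueError("flags and zscores must have equal length")

    @property
    def n_windows(self) -> int:
        return self.flags.size

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def clean_sample_mask(self, fs: float, n_samples: int) -> np.ndarray:
        """True for samples inside unflagged full windows."""
        mask = np.zeros(n_samples, dtype=bool)
        wlen = int(round(self.window_len * fs))
        for w in np.flatnonzero(~self.flags):
            mask[w * wlen : (w + 1) * wlen] = True
        return mask

    @classmethod
    def all_clean(cls, duration_s: float, window_len: float = 5.0) -> "ArtifactMask":
        n = int(duration_s // window_len)
        return cls(flags=np.zeros(n, dtype=bool), zscores=np.zeros(n), window_len=window_len)


@dataclass
class SleepEvent:
    """A detected slow oscillation or spindle.

    ``amplitude`` is peak-to-peak µV for SOs and peak RMS µV for spindles.
    """

    kind: str  # "SO" | "spindle"
    onset: float  # s from recording start
    duration: float  # s
    amplitude: float  # µV
    stage: str
    channel: str

    def __post_init__(self) -> None:
        if self.kind not in ("SO", "spindle"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
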