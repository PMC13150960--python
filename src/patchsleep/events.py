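"""Slow-oscillation and spindle detection, and event densities.

Both detectors run on the staging EEG channel (EEG Ch1) at 100 Hz and operate
only inside artifact-free epochs of the relevant stages.

Slow oscillations: the signal is band-passed 0.5–1.5 Hz; every pair of
consecutive down-going zero crossings enclosing a negative then a positive
half-wave is a candidate; candidates lasting 0.5–2 s are kept when their
trough-to-peak amplitude exceeds the 75th percentile of the night's candidate
pool (pooled per night, per channel, within NREM).

Spindles: the signal is band-passed 12–16 Hz; a 0.3-s RMS envelope is computed
in 0.1-s steps over the artifact-free epochs of one stage (N2 or N3); windows
whose RMS exceeds the stage's mean + 1.5 SD form candidate runs; maximal runs
whose covered span lasts 0.5–2 s become spindles. The threshold is recomputed
per night and stage from the data, so detection is invariant to global
amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ArtifactMask, Hypnogram, NREM_STAGES, SleepEvent
from .preprocess import bandpass_array


@dataclass
class DetectorParams:
    so_band: tuple[float, float] = (0.5, 1.5)
    so_amp_percentile: float = 75.0
    spindle_band: tuple[float, float] = (12.0, 16.0)
    rms_window: float = 0.3  # s
    rms_step: float = 0.1  # s
    rms_threshold_sd: float = 1.5
    duration_bounds: tuple[float, float] = (0.5, 2.0)  # s

    def __post_init__(self) -> None:
        if not 0 < self.so_amp_percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        for v in (*self.so_band, *self.spindle_band, self.rms_window, self.rms_step,
                  self.rms_threshold_sd, *self.duration_bounds):
            if v <= 0:
                raise ValueError("detector parameters must be positive")


@dataclass
class SoCandidate:
    """One zero-crossing-bounded wave, retained for audit of the percentile rule."""

    onset: float
    duration: float
    amplitude: float  # trough-to-peak, µV
    stage: str
    kept: bool = False


@dataclass
class SoDetectionResult:
    events: list[SleepEvent]
    candidates: list[SoCandidate] = field(default_factory=list)
    amplitude_threshold: float = float("nan")  # the pool's 75th percentile


def _stage_clean_mask(
    hypnogram: Hypnogram,
    stages: tuple[str, ...],
    artifact_mask: ArtifactMask,
    fs: float,
    n_samples: int,
) -> np.ndarray:
    mask = hypnogram.sample_mask(fs, n_samples, stages)
    mask &= artifact_mask.clean_sample_mask(fs, n_samples)
    return mask


def detect_slow_oscillations(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    artifact_mask: ArtifactMask,
    params: DetectorParams | None = None,
    channel: str = "EEG Ch1",
) -> SoDetectionResult:
    """Detect slow oscillations within artifact-free NREM sleep."""
    params = params or DetectorParams()
    x = np.asarray(signal, dtype=float)
    nrem = hypnogram.epochs_of(*NREM_STAGES)
    if nrem.size == 0:
        return SoDetectionResult(events=[])
    valid = _stage_clean_mask(hypnogram, NREM_STAGES, artifact_mask, fs, x.size)
    filt = bandpass_array(x, fs, *params.so_band)

    # down-going zero crossings: filt[i] >= 0 and filt[i+1] < 0
    down = np.flatnonzero((filt[:-1] >= 0) & (filt[1:] < 0))
    lo, hi = params.duration_bounds
    stages = hypnogram.stage_array()
    spe = int(round(hypnogram.epoch_len * fs))

    candidates: list[SoCandidate] = []
    for c0, c1 in zip(down[:-1], down[1:]):
        dur = (c1 - c0) / fs
        if not (lo <= dur <= hi):
            continue
        if not valid[c0 : c1 + 1].all():
            continue
        seg = filt[c0 : c1 + 1]
        up = np.flatnonzero((seg[:-1] < 0) & (seg[1:] >= 0))
        if up.size == 0:
            continue  # never returns positive: no biphasic wave
        u = int(up[0])
        trough = float(seg[: u + 1].min())
        peak = float(seg[u:].max())
        if trough >= 0 or peak <= 0:
            continue
        epoch_i = min(int(c0 // spe), len(stages) - 1)
        candidates.append(
            SoCandidate(
                onset=c0 / fs, duration=dur, amplitude=peak - trough, stage=str(stages[epoch_i])
            )
        )

    if not candidates:
        return SoDetectionResult(events=[])
    amps = np.array([c.amplitude for c in candidates])
    threshold = float(np.percentile(amps, params.so_amp_percentile))
    events = []
    for cand in candidates:
        if cand.amplitude > threshold:
            cand.kept = True
            events.append(
                SleepEvent(
                    kind="SO",
                    onset=cand.onset,
                    duration=cand.duration,
                    amplitude=cand.amplitude,
                    stage=cand.stage,
                    channel=channel,
                )
            )
    return SoDetectionResult(events=events, candidates=candidates, amplitude_threshold=threshold)


def detect_spindles(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    stage: str,
    artifact_mask: ArtifactMask,
    params: DetectorParams | None = None,
    channel: str = "EEG Ch1",
) -> list[SleepEvent]:
    """Detect spindles within artifact-free epochs of one stage (N2 or N3)."""
    params = params or DetectorParams()
    if stage not in ("N1", "N2", "N3", "REM", "W"):
        raise ValueError(f"unknown stage {stage!r}")
    x = np.asarray(signal, dtype=float)
    if hypnogram.epochs_of(stage).size == 0:
        return []
    valid = _stage_clean_mask(hypnogram, (stage,), artifact_mask, fs, x.size)
    filt = bandpass_array(x, fs, *params.spindle_band)

    win = int(round(params.rms_window * fs))
    hop = int(round(params.rms_step * fs))
    starts = np.arange(0, x.size - win + 1, hop)
    if starts.size == 0:
        return []
    # windows fully inside valid spans; RMS via cumulative sums
    cs2 = np.concatenate([[0.0], np.cumsum(filt**2)])
    csv = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    full_valid = (csv[starts + win] - csv[starts]) == win
    rms = np.sqrt((cs2[starts + win] - cs2[starts]) / win)

    vstarts = starts[full_valid]
    vrms = rms[full_valid]
    if vrms.size < 2:
        return []
    threshold = vrms.mean() + params.rms_threshold_sd * vrms.std()
    supra = vrms > threshold

    lo, hi = params.duration_bounds
    events: list[SleepEvent] = []
    i = 0
    while i < supra.size:
        if not supra[i]:
            i += 1
            continue
        j = i
        # extend over consecutive windows (adjacent start times, one hop apart)
        while j + 1 < supra.size and supra[j + 1] and vstarts[j + 1] - vstarts[j] == hop:
            j += 1
        onset = vstarts[i] / fs
        # duration = time the RMS stays above threshold (span of suprathreshold
        # window positions); the covered-span alternative inflates noise runs
        duration = (vstarts[j] - vstarts[i]) / fs
        if lo <= duration <= hi:
            events.append(
                SleepEvent(
                    kind="spindle",
                    onset=onset,
                    duration=duration,
                    amplitude=float(vrms[i : j + 1].max()),
                    stage=stage,
                    channel=channel,
                )
            )
        i = j + 1
    return events


def so_density(events: list[SleepEvent], nrem_minutes_clean: float) -> float:
    """Slow oscillations per artifact-free NREM minute."""
    if nrem_minutes_clean <= 0:
        raise ValueError("NREM minutes must be positive for a density")
    return len(events) / nrem_minutes_clean


def spindle_density(events: list[SleepEvent], stage_minutes_clean: float) -> float:
    """Spindles per artifact-free minute of the stage."""
    if stage_minutes_clean <= 0:
        raise ValueError("stage minutes must be positive for a density")
    return len(events) / stage_minutes_clean


def clean_stage_minutes(
    hypnogram: Hypnogram, stages: tuple[str, ...], artifact_mask: ArtifactMask, fs: float, n_samples: int
) -> float:
    """Artifact-free minutes spent in ``stages`` (density denominator)."""
    mask = _stage_clean_mask(hypnogram, stages, artifact_mask, fs, n_samples)
    return float(mask.sum() / fs / 60.0)
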