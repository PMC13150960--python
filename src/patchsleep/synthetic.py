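"""Synthetic multi-night, two-group sleep-EEG cohorts with known ground truth.

The generator emulates what the analysis pipeline needs to see, not sleep
physiology: a stage-structured hypnogram (wake latency, NREM-REM cycles with
N3 decaying and REM growing across cycles), four channels of 1/f background
noise with stage-scaled RMS, and injected events — biphasic slow oscillations
in N3, Tukey-windowed 12–16 Hz spindle bursts in N2/N3, large opposite-polarity
EOG deflections in REM, alpha plus common-mode movement bursts in wake.
Every injected event is logged as ground truth. Two-group defaults mirror the
age contrasts the pipeline must recover: the older group's N3 dwell is about
half and its N2 spindle rate about a third of the young group's.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal.windows import tukey

from .containers import Hypnogram, Recording, CHANNEL_LABELS
from .io_formats import DISPOSITIONS, write_edf, write_hypnogram, write_manifest

SO_FREQ_HZ = 0.75  # one period of this sine is the injected SO waveform
SO_DURATION_S = 1.0 / SO_FREQ_HZ
EEG2_GAIN = 0.9  # second EEG channel sees a slightly attenuated copy of events


@dataclass
class StageParams:
    """Signal content of one sleep stage. Rates are events/min, amplitudes µV."""

    stage: str
    background_amp: float = 12.0  # RMS of the 1/f background
    so_rate: float = 0.0
    so_amp: float = 0.0  # peak-to-peak
    spindle_rate: float = 0.0
    spindle_amp: float = 0.0  # envelope peak
    spindle_freq_range: tuple[float, float] = (12.0, 15.0)
    alpha_amp: float = 0.0  # 10-Hz sine amplitude
    rem_eog_rate: float = 0.0
    rem_eog_amp: float = 100.0
    movement_rate: float = 0.0
    movement_amp: float = 0.0  # RMS of common-mode burst noise

    def __post_init__(self) -> None:
        for name in ("background_amp", "so_rate", "so_amp", "spindle_rate", "spindle_amp",
                     "alpha_amp", "rem_eog_rate", "rem_eog_amp", "movement_rate", "movement_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.spindle_freq_range
        if not (12.0 <= lo < hi <= 16.0):
            raise ValueError(f"spindle_freq_range {self.spindle_freq_range} must lie within [12, 16] Hz")


@dataclass
class HypnogramParams:
    """Cycle structure of the generated hypnogram (all dwell means in 30-s epochs)."""

    wake_latency_mean: float = 20.0
    n1_mean: float = 3.5
    n2_mean: float = 45.0
    n2b_frac: float = 0.4  # post-N3 return to N2, as a fraction of n2_mean
    n3_mean: float = 66.0
    n3_decay: float = 0.55  # per-cycle multiplier on the N3 dwell
    rem_mean: float = 14.0
    rem_growth: float = 1.15  # per-cycle multiplier on the REM dwell
    brief_wake_mean: float = 24.0  # WASO bout after each cycle
    brief_wake_prob: float = 0.9


@dataclass
class GroundTruth:
    """Everything the generator injected into one night."""

    true_hypnogram: Hypnogram
    so_events: list[tuple[float, float, float]] = field(default_factory=list)  # onset, dur, ptp µV
    spindle_events: list[tuple[float, float, str]] = field(default_factory=list)  # onset, dur, stage
    artifact_spans: list[tuple[float, float, str]] = field(default_factory=list)  # onset, dur, kind
    disposition: str = "usable"


@dataclass
class GroupConfig:
    stage_params: dict[str, StageParams]
    hypnogram_params: HypnogramParams


@dataclass
class CohortSpec:
    n_per_group: int = 12
    nights_per_participant: int = 7  # one week of home wear
    epochs_per_night: int = 960  # 8 h
    fs: float = 250.0
    groups: dict[str, GroupConfig] = field(default_factory=lambda: default_group_configs())
    loss_probs: dict[str, float] = field(
        default_factory=lambda: {"usable": 1.0, "not_worn": 0.0,
                                 "poor_reference_adhesion": 0.0, "bluetooth": 0.0}
    )
    subject_sd: float = 0.15  # lognormal sd of between-participant factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        bad = set(self.loss_probs) - set(DISPOSITIONS)
        if bad:
            raise ValueError(f"unknown loss categories {sorted(bad)}; allowed {DISPOSITIONS}")
        probs = np.array([self.loss_probs.get(c, 0.0) for c in DISPOSITIONS])
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("loss probabilities must lie in [0, 1] and sum to 1")


def default_stage_params(group: str = "young") -> dict[str, StageParams]:
    """Stage signal content calibrated so group contrasts track the expected
    age effects: the old group's N2 spindle rate is about one third of the
    young group's (the N3 dwell contrast lives in the hypnogram parameters)."""
    young = group == "young"
    return {
        "W": StageParams(stage="W", background_amp=15.0, alpha_amp=15.0,
                         movement_rate=0.5, movement_amp=200.0),
        "N1": StageParams(stage="N1", background_amp=12.0, alpha_amp=4.0),
        "N2": StageParams(stage="N2", background_amp=12.0,
                          spindle_rate=3.0 if young else 1.0, spindle_amp=10.0,
                          so_rate=0.5, so_amp=80.0),
        "N3": StageParams(stage="N3", background_amp=20.0,
                          so_rate=5.0, so_amp=150.0,
                          spindle_rate=0.3 if young else 0.1, spindle_amp=8.0),
        "REM": StageParams(stage="REM", background_amp=10.0,
                           rem_eog_rate=10.0, rem_eog_amp=100.0),
        "UNSCORED": StageParams(stage="UNSCORED", background_amp=12.0),
    }


def default_hypnogram_params(group: str = "young") -> HypnogramParams:
    """Dwell structure calibrated (Monte-Carlo over seeds) so that generated
    stage shares track the expected group contrast: old N3 about half of
    young, more N2 and wake, slightly less REM."""
    if group == "young":
        return HypnogramParams()
    return HypnogramParams(
        wake_latency_mean=28.0, n1_mean=4.0, n2_mean=50.0, n3_mean=38.0, n3_decay=0.5,
        rem_mean=11.5, rem_growth=1.1, brief_wake_mean=29.0, brief_wake_prob=0.9,
    )


def default_group_configs() -> dict[str, GroupConfig]:
    return {
        g: GroupConfig(stage_params=default_stage_params(g),
                       hypnogram_params=default_hypnogram_params(g))
        for g in ("young", "old")
    }


def _dwell(rng: np.random.Generator, mean: float) -> int:
    """Truncated-normal dwell draw in epochs, clipped to [0.5, 1.5] x mean."""
    if mean <= 0:
        return 0
    d = rng.normal(mean, 0.25 * mean)
    return int(round(np.clip(d, 0.5 * mean, 1.5 * mean)))


def generate_hypnogram(
    params: HypnogramParams, total_epochs: int, seed: int
) -> Hypnogram:
    """Stage-structured night: wake latency, then NREM-REM cycles with brief
    awakenings; N3 decays and REM grows across cycles. Deterministic per seed."""
    if total_epochs < 1:
        raise ValueError(f"total_epochs must be >= 1, got {total_epochs}")
    rng = np.random.default_rng(seed)
    stages: list[str] = []
    stages += ["W"] * max(1, _dwell(rng, params.wake_latency_mean))
    cycle = 0
    while len(stages) < total_epochs:
        decay = params.n3_decay**cycle
        growth = params.rem_growth**cycle
        stages += ["N1"] * max(1, _dwell(rng, params.n1_mean))
        stages += ["N2"] * max(1, _dwell(rng, params.n2_mean))
        stages += ["N3"] * _dwell(rng, params.n3_mean * decay)
        stages += ["N2"] * _dwell(rng, params.n2_mean * params.n2b_frac)
        stages += ["REM"] * max(1, _dwell(rng, params.rem_mean * growth))
        if rng.uniform() < params.brief_wake_prob:
            stages += ["W"] * _dwell(rng, params.brief_wake_mean)
        cycle += 1
    return Hypnogram(stages=stages[:total_epochs])


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, f_floor: float = 0.5) -> np.ndarray:
    """Unit-RMS noise with power ∝ 1/f above ``f_floor`` (flat below)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_floor))
    amp[0] = 0.0
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * amp
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _place(
    rng: np.random.Generator, occupied: list[tuple[float, float]], dur: float,
    epoch_len: float = 30.0, gap: float = 1.0, tries: int = 40,
) -> float | None:
    """Uniform onset within the epoch avoiding existing events by >= ``gap`` s."""
    if dur >= epoch_len:
        return None
    for _ in range(tries):
        onset = rng.uniform(0.0, epoch_len - dur)
        if all(onset >= e + gap or onset + dur <= s - gap for s, e in occupied):
            occupied.append((onset, onset + dur))
            return onset
    return None


def synthesize_night(
    hypnogram: Hypnogram,
    stage_params: dict[str, StageParams],
    fs: float = 250.0,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Render one night of 4-channel signal from a hypnogram, logging all
    injected events. Zero-amplitude events consume the same random draws, so
    an events-off rendering under the same seed shares the background exactly."""
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    if hypnogram.n_epochs == 0:
        raise ValueError("hypnogram must be non-empty")
    for label in set(hypnogram.stages):
        if label not in stage_params:
            raise KeyError(f"no stage parameters for stage label {label!r}")

    epoch_len = hypnogram.epoch_len
    spe = int(round(epoch_len * fs))
    n = hypnogram.n_epochs * spe
    bg_seq, ev_seq = np.random.SeedSequence(seed).spawn(2)
    bg_rng = np.random.default_rng(bg_seq)
    rng = np.random.default_rng(ev_seq)

    samples = np.empty((4, n))
    for ch in range(4):
        samples[ch] = _one_over_f_noise(bg_rng, n, fs)
    # stage-scaled background RMS
    amps = np.array([stage_params[s].background_amp for s in hypnogram.stages])
    samples *= np.repeat(amps, spe)[None, :]

    truth = GroundTruth(true_hypnogram=hypnogram)
    eeg1, eeg2, eog1, eog2 = samples

    for i, stage in enumerate(hypnogram.stages):
        p = stage_params[stage]
        t0 = i * epoch_len
        sl0 = i * spe
        occupied: list[tuple[float, float]] = []

        if p.alpha_amp >= 0:  # draw phase unconditionally to keep streams aligned
            phase = rng.uniform(0, 2 * np.pi)
            if p.alpha_amp > 0:
                t = np.arange(spe) / fs
                alpha = p.alpha_amp * np.sin(2 * np.pi * 10.0 * t + phase)
                eeg1[sl0 : sl0 + spe] += alpha
                eeg2[sl0 : sl0 + spe] += EEG2_GAIN * alpha

        for _ in range(rng.poisson(p.so_rate * epoch_len / 60.0)):
            amp = p.so_amp * (1.0 + rng.uniform(-0.2, 0.2))
            onset = _place(rng, occupied, SO_DURATION_S, epoch_len)
            if onset is None:
                continue
            k = int(round(SO_DURATION_S * fs))
            wave = -(amp / 2.0) * np.sin(2 * np.pi * SO_FREQ_HZ * np.arange(k) / fs)
            j = sl0 + int(round(onset * fs))
            eeg1[j : j + k] += wave
            eeg2[j : j + k] += EEG2_GAIN * wave
            if amp > 0:
                truth.so_events.append((t0 + onset, SO_DURATION_S, amp))

        for _ in range(rng.poisson(p.spindle_rate * epoch_len / 60.0)):
            dur = rng.uniform(0.5, 1.5)
            freq = rng.uniform(*p.spindle_freq_range)
            phase = rng.uniform(0, 2 * np.pi)
            onset = _place(rng, occupied, dur, epoch_len)
            if onset is None:
                continue
            k = int(round(dur * fs))
            env = tukey(k, 0.5) * p.spindle_amp
            wave = env * np.sin(2 * np.pi * freq * np.arange(k) / fs + phase)
            j = sl0 + int(round(onset * fs))
            eeg1[j : j + k] += wave
            eeg2[j : j + k] += EEG2_GAIN * wave
            if p.spindle_amp > 0:
                truth.spindle_events.append((t0 + onset, dur, stage))

        eog_occupied: list[tuple[float, float]] = []
        for _ in range(rng.poisson(p.rem_eog_rate * epoch_len / 60.0)):
            dur = rng.uniform(0.4, 0.8)
            onset = _place(rng, eog_occupied, dur, epoch_len, gap=0.5)
            if onset is None:
                continue
            k = int(round(dur * fs))
            bump = p.rem_eog_amp * np.sin(np.pi * np.arange(k) / k)
            j = sl0 + int(round(onset * fs))
            eog1[j : j + k] += bump
            eog2[j : j + k] -= bump  # opposite polarity across the eyes

        for _ in range(rng.poisson(p.movement_rate * epoch_len / 60.0)):
            dur = rng.uniform(1.0, 3.0)
            onset = _place(rng, occupied, dur, epoch_len)
            if onset is None:
                continue
            k = int(round(dur * fs))
            burst = p.movement_amp * rng.standard_normal(k) * tukey(k, 0.5)
            j = sl0 + int(round(onset * fs))
            for ch in samples:  # common-mode: movement shakes every electrode
                ch[j : j + k] += burst
            if p.movement_amp > 0:
                truth.artifact_spans.append((t0 + onset, dur, "movement"))

    rec = Recording(samples=samples, fs=fs, channel_labels=CHANNEL_LABELS,
                    meta={"synthetic": True, "seed": seed})
    return rec, truth


def emulate_data_loss(
    recording: Recording, disposition: str, seed: int = 0
) -> tuple[Recording, list[tuple[float, float, str]]]:
    """Degrade a night according to its loss category.

    not_worn empties the recording; bluetooth truncates it below the 5-h
    retention gate; poor_reference_adhesion corrupts spans (flatline and
    broadband noise on every channel — the reference is common) and ends the
    record early, leaving under 5 h. Returns the recording and the corrupted
    spans. ``usable`` is the identity.
    """
    if disposition not in DISPOSITIONS:
        raise ValueError(f"unknown disposition {disposition!r}; allowed {DISPOSITIONS}")
    if disposition == "usable":
        return recording, []
    rng = np.random.default_rng(seed)
    if disposition == "not_worn":
        empty = Recording(
            samples=np.zeros((recording.n_channels, 0)), fs=recording.fs,
            channel_labels=tuple(recording.channel_labels),
            start_time=recording.start_time, meta={"disposition": disposition},
        )
        return empty, []
    dur = recording.duration_s
    if disposition == "bluetooth":
        t_end = min(rng.uniform(0.5, 4.5) * 3600.0, 0.9 * dur)
        out = recording.copy_with(recording.samples[:, : int(t_end * recording.fs)].copy())
        out.meta["disposition"] = disposition
        return out, []
    # poor_reference_adhesion
    t_end = min(rng.uniform(1.0, 4.9) * 3600.0, 0.9 * dur)
    n_end = int(t_end * recording.fs)
    x = recording.samples[:, :n_end].copy()
    spans = []
    for k in range(int(rng.integers(2, 6))):
        span = min(rng.uniform(30.0, 300.0), 0.5 * t_end)
        onset = rng.uniform(0.0, t_end - span)
        a = int(onset * recording.fs)
        b = min(int((onset + span) * recording.fs), n_end)
        if k % 2 == 0:
            x[:, a:b] *= 0.01  # electrode lift-off: near flatline
        else:
            x[:, a:b] += rng.normal(0.0, 300.0, size=(x.shape[0], b - a))
        spans.append((float(onset), float(span), "flatline" if k % 2 == 0 else "movement"))
    out = recording.copy_with(x)
    out.meta["disposition"] = disposition
    return out, spans


def _jitter_group(
    cfg: GroupConfig, rng: np.random.Generator, sd: float
) -> GroupConfig:
    """Per-participant multiplicative heterogeneity on dwell means and rates."""
    f = {k: float(rng.lognormal(0.0, sd)) for k in ("n3", "rem", "wake", "spindle", "so")}
    hp = replace(
        cfg.hypnogram_params,
        n3_mean=cfg.hypnogram_params.n3_mean * f["n3"],
        rem_mean=cfg.hypnogram_params.rem_mean * f["rem"],
        wake_latency_mean=cfg.hypnogram_params.wake_latency_mean * f["wake"],
        brief_wake_mean=cfg.hypnogram_params.brief_wake_mean * f["wake"],
    )
    sp = {}
    for stage, p in cfg.stage_params.items():
        sp[stage] = replace(p, spindle_rate=p.spindle_rate * f["spindle"],
                            so_rate=p.so_rate * f["so"])
    return GroupConfig(stage_params=sp, hypnogram_params=hp)


def _truth_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [{"kind": "SO", "onset": o, "duration": d, "amplitude": a, "stage": ""}
            for o, d, a in truth.so_events]
    rows += [{"kind": "spindle", "onset": o, "duration": d, "amplitude": np.nan, "stage": s}
             for o, d, s in truth.spindle_events]
    rows += [{"kind": f"artifact_{k}", "onset": o, "duration": d, "amplitude": np.nan, "stage": ""}
             for o, d, k in truth.artifact_spans]
    return pd.DataFrame(rows, columns=["kind", "onset", "duration", "amplitude", "stage"])


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a full synthetic cohort (EDF + hypnogram + ground truth per night)
    and return its manifest (also written as ``manifest.csv``)."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / ".write_test").write_text("")
        (out_dir / ".write_test").unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    cats = list(DISPOSITIONS)
    probs = np.array([spec.loss_probs.get(c, 0.0) for c in cats])
    root = np.random.SeedSequence(spec.seed)
    rows = []
    for group in sorted(spec.groups):
        cfg = spec.groups[group]
        for pi in range(spec.n_per_group):
            pid = f"{group}{pi + 1:02d}"
            p_seq = root.spawn(1)[0]
            p_rng = np.random.default_rng(p_seq)
            p_cfg = _jitter_group(cfg, p_rng, spec.subject_sd)
            for night in range(1, spec.nights_per_participant + 1):
                hyp_seed, night_seed, loss_seed = [s.generate_state(1)[0] % (2**31)
                                                   for s in p_seq.spawn(3)]
                disposition = cats[p_rng.choice(len(cats), p=probs)]
                hyp = generate_hypnogram(p_cfg.hypnogram_params, spec.epochs_per_night,
                                         seed=int(hyp_seed))
                true_tst = hyp.minutes_of("N1", "N2", "N3", "REM")
                actigraphy = round(float(true_tst * p_rng.uniform(0.92, 1.05)), 1)
                stem = f"{pid}_n{night}"
                if disposition == "not_worn":
                    rows.append({
                        "participant_id": pid, "group": group, "night_index": night,
                        "recording_path": "", "hypnogram_path": "",
                        "disposition": disposition, "actigraphy_tst_min": actigraphy,
                    })
                    continue
                rec, truth = synthesize_night(hyp, p_cfg.stage_params, fs=spec.fs,
                                              seed=int(night_seed))
                rec, spans = emulate_data_loss(rec, disposition, seed=int(loss_seed))
                truth.artifact_spans.extend(spans)
                truth.disposition = disposition
                rec_path = out_dir / f"{stem}.edf"
                hyp_path = out_dir / f"{stem}.hyp.txt"
                write_edf(rec, rec_path)
                write_hypnogram(hyp, hyp_path)
                _truth_frame(truth).to_csv(out_dir / f"{stem}.truth.csv", index=False)
                rows.append({
                    "participant_id": pid, "group": group, "night_index": night,
                    "recording_path": rec_path.name, "hypnogram_path": hyp_path.name,
                    "disposition": disposition, "actigraphy_tst_min": actigraphy,
                })
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


# -- cohort spec (de)serialization -------------------------------------------


def spec_to_yaml(spec: CohortSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def spec_from_yaml(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    groups = {}
    for g, gc in d.pop("groups", {}).items():
        sp = {s: StageParams(**{**p, "spindle_freq_range": tuple(p["spindle_freq_range"])})
              for s, p in gc["stage_params"].items()}
        groups[g] = GroupConfig(stage_params=sp,
                                hypnogram_params=HypnogramParams(**gc["hypnogram_params"]))
    return CohortSpec(groups=groups, **d)
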