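"""Per-night processing and cohort orchestration.

``run_night`` applies the full per-recording chain: QC filters (0.3–35 Hz
band-pass, 59–61 Hz notch while still above the line frequency), the 5-hour
retention gate, downsampling to 100 Hz, covariance artifact masking, staging
ingestion, slow-oscillation and spindle detection, stage-wise spectral
summaries and the night's macro metrics. ``run_cohort`` maps it over a
manifest, aggregates per participant, builds the retention ledger and runs the
group comparison; a failing night never aborts the cohort.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io_formats, preprocess, spectral, staging
from .containers import CHANNEL_LABELS, Hypnogram, NREM_STAGES, Recording
from .events import (DetectorParams, clean_stage_minutes, detect_slow_oscillations,
                     detect_spindles, so_density, spindle_density)
from .stats import GroupComparison, compare_groups, comparison_frame
from .summary import (NightSummary, ParticipantSummary, aggregate_participant,
                      build_retention_ledger, participants_frame, score_night)

log = logging.getLogger("patchsleep")

#: Measures compared between groups, in reporting order.
COMPARISON_MEASURES = [
    "tst_min", "sleep_efficiency", "pct_n1", "pct_n2", "pct_n3", "pct_rem",
    "so_density", "nrem_rel_delta", "spindle_density_n2", "spindle_density_n3",
]


@dataclass
class RunConfig:
    qc_band: tuple[float, float] = (0.3, 35.0)
    notch_band: tuple[float, float] = (59.0, 61.0)
    target_fs: float = 100.0
    artifact_window: float = 5.0
    artifact_z: float = 3.0
    psd_band: tuple[float, float] = (0.5, 45.0)
    detector: DetectorParams = field(default_factory=DetectorParams)
    stager: str = "file"  # "file" | "naive"
    min_hours: float = 5.0
    staging_channel: str = "EEG Ch1"
    seed: int = 0


@dataclass
class NightResult:
    participant_id: str
    night_index: int
    disposition: str  # "usable" | gate/failure reason
    summary: NightSummary | None = None
    so_events: list = field(default_factory=list)
    spindle_events: list = field(default_factory=list)
    error: str | None = None


def process_recording(
    recording: Recording,
    hypnogram: Hypnogram | None,
    config: RunConfig | None = None,
    actigraphy_tst_min: float | None = None,
) -> NightResult:
    """Run the per-night chain on in-memory objects (see module docstring)."""
    config = config or RunConfig()
    result = NightResult(participant_id="", night_index=0, disposition="usable")

    missing = set(CHANNEL_LABELS) - set(recording.channel_labels)
    if missing:
        raise ValueError(f"recording lacks required channels {sorted(missing)}")

    keep, reason = preprocess.quality_gate(
        recording, actigraphy_tst_min=actigraphy_tst_min, min_hours=config.min_hours
    )
    if not keep:
        result.disposition = reason
        return result

    rec = preprocess.bandpass(recording, *config.qc_band)
    if rec.fs > 2 * config.notch_band[1]:
        rec = preprocess.notch(rec, config.notch_band)
    rec = preprocess.resample(rec, config.target_fs)

    mask = preprocess.detect_artifacts(rec, config.artifact_window, config.artifact_z)

    if config.stager == "naive" or hypnogram is None:
        eeg, eog = staging.stager_input_from_recording(rec)
        hyp = staging.naive_stage(eeg, eog, rec.fs)
    else:
        hyp = staging.ingest_hypnogram(hypnogram, rec)

    x = rec.channel(config.staging_channel)
    so_res = detect_slow_oscillations(x, rec.fs, hyp, mask, config.detector,
                                      channel=config.staging_channel)
    sp_n2 = detect_spindles(x, rec.fs, hyp, "N2", mask, config.detector,
                            channel=config.staging_channel)
    sp_n3 = detect_spindles(x, rec.fs, hyp, "N3", mask, config.detector,
                            channel=config.staging_channel)

    summary = NightSummary()
    summary.__dict__.update(score_night(hyp, recording.duration_s / 60.0))

    nrem_min = clean_stage_minutes(hyp, NREM_STAGES, mask, rec.fs, rec.n_samples)
    n2_min = clean_stage_minutes(hyp, ("N2",), mask, rec.fs, rec.n_samples)
    n3_min = clean_stage_minutes(hyp, ("N3",), mask, rec.fs, rec.n_samples)
    if nrem_min > 0:
        summary.so_density = so_density(so_res.events, nrem_min)
    if n2_min > 0:
        summary.spindle_density_n2 = spindle_density(sp_n2, n2_min)
    if n3_min > 0:
        summary.spindle_density_n3 = spindle_density(sp_n3, n3_min)

    # stage-segmented relative band powers on 0.5-45 Hz filtered data
    psd_sig = preprocess.bandpass_array(x, rec.fs, *config.psd_band)
    clean = mask.clean_sample_mask(rec.fs, rec.n_samples)
    rel = {}
    for stage in ("N2", "N3"):
        smask = hyp.sample_mask(rec.fs, rec.n_samples, (stage,)) & clean
        seg = psd_sig[smask]
        if seg.size >= int(4.0 * rec.fs):
            rel[stage] = spectral.relative_band_power(spectral.welch_psd(seg, rec.fs))
    summary.rel_power = rel
    if "N2" in rel and "N3" in rel and (n2_min + n3_min) > 0:
        summary.nrem_rel_delta = spectral.composite_nrem_delta(
            rel["N2"]["delta"], rel["N3"]["delta"], n2_min, n3_min
        )
    elif "N2" in rel:
        summary.nrem_rel_delta = rel["N2"]["delta"]
    elif "N3" in rel:
        summary.nrem_rel_delta = rel["N3"]["delta"]

    try:
        summary.snr_db = spectral.compute_snr_db(rec, hyp, mask, channel=config.staging_channel)
    except ValueError as exc:
        log.warning("SNR undefined: %s", exc)

    result.summary = summary
    result.so_events = so_res.events
    result.spindle_events = sp_n2 + sp_n3
    return result


def run_night(
    recording_path: str | Path,
    hypnogram_path: str | Path | None,
    config: RunConfig | None = None,
    actigraphy_tst_min: float | None = None,
) -> NightResult:
    """Load one night from disk and process it."""
    recording = io_formats.read_edf(recording_path)
    hypnogram = None
    if hypnogram_path:
        hypnogram = io_formats.read_hypnogram(hypnogram_path)
    return process_recording(recording, hypnogram, config, actigraphy_tst_min)


def run_cohort(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    data_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Process every manifest night; aggregate, account retention, compare groups.

    Nights marked lost in the manifest, failing the gate, or raising during
    processing are logged and excluded; their dispositions feed the retention
    ledger. Participants with zero usable nights are excluded from the
    comparison (and counted in the ledger).
    """
    config = config or RunConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        manifest = io_formats.read_manifest(manifest_path)
        data_dir = data_dir or manifest_path.parent
    data_dir = Path(data_dir) if data_dir is not None else Path(".")

    night_results: list[NightResult] = []
    observed_disposition: list[str] = []
    for row in manifest.itertuples(index=False):
        if row.disposition == "not_worn":
            observed_disposition.append("not_worn")
            night_results.append(NightResult(row.participant_id, row.night_index,
                                             disposition="not_worn"))
            continue
        try:
            res = run_night(
                data_dir / row.recording_path,
                (data_dir / row.hypnogram_path) if row.hypnogram_path else None,
                config,
                actigraphy_tst_min=(None if pd.isna(row.actigraphy_tst_min)
                                    else float(row.actigraphy_tst_min)),
            )
            res.participant_id, res.night_index = row.participant_id, row.night_index
        except Exception as exc:  # one bad night never sinks the cohort
            log.error("night %s/%s failed: %s", row.participant_id, row.night_index, exc)
            log.debug("%s", traceback.format_exc())
            res = NightResult(row.participant_id, row.night_index,
                              disposition="unreadable", error=str(exc))
        night_results.append(res)
        observed_disposition.append(
            "usable" if res.summary is not None else str(row.disposition)
        )

    # retention uses manifest dispositions (ground truth of what happened)
    ledger = build_retention_ledger(manifest)

    by_participant: dict[str, list[NightSummary]] = {}
    for res in night_results:
        if res.summary is not None:
            res.summary.participant_id = res.participant_id
            res.summary.night_index = res.night_index
            by_participant.setdefault(res.participant_id, []).append(res.summary)

    groups = manifest.drop_duplicates("participant_id").set_index("participant_id")["group"]
    summaries: list[ParticipantSummary] = []
    for pid, nights in sorted(by_participant.items()):
        summaries.append(aggregate_participant(nights, participant_id=pid,
                                               group=str(groups.get(pid, ""))))
    pf = participants_frame(summaries)

    comparisons: list[GroupComparison] = []
    if len(pf) and pf["group"].nunique() >= 2:
        counts = pf["group"].value_counts()
        if (counts >= 1).sum() >= 2:
            comparisons = compare_groups(pf, COMPARISON_MEASURES)
    else:
        log.warning("fewer than two groups with usable participants; comparison skipped")

    out = {
        "night_results": night_results,
        "participants": pf,
        "ledger": ledger,
        "comparisons": comparisons,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pf.to_csv(out_dir / "participants.csv", index=False)
        comparison_frame(comparisons).to_csv(out_dir / "group_comparison.csv", index=False)
        from .summary import format_retention_ledger, ledger_frame

        ledger_frame(ledger).to_csv(out_dir / "retention_ledger.csv", index=False)
        (out_dir / "retention_ledger.txt").write_text(format_retention_ledger(ledger))
    return out
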