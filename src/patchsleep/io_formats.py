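"""On-disk formats: EDF recordings, the patch app's CSV dialect, hypnograms, manifests.

EDF here is plain EDF (not EDF+): fixed 256-byte header, one 256-byte header
block per signal, 1-second data records of little-endian 16-bit integers
scaled between per-channel physical and digital ranges. Physical units are µV.

The patch app's CSV dialect (the deployed schema is not published; this is the
package's own definition, see README): an optional comment line ``# fs=<Hz>``,
a header row ``sample_index,<channel>,...``, then one row per sample with
values in µV. Long recordings may be rotated across several files sharing a
common prefix and a numeric suffix; segments are concatenated by sample index,
and missing indices become NaN sentinels with the gap spans recorded in
``Recording.meta["gaps"]`` (never interpolated).
"""

from __future__ import annotations

import csv
import glob
import io
import os
import re
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import STAGES, CHANNEL_LABELS, Hypnogram, Recording

#: Fixed disposition vocabulary for cohort manifests.
DISPOSITIONS = ("usable", "not_worn", "poor_reference_adhesion", "bluetooth")

MANIFEST_COLUMNS = (
    "participant_id",
    "group",
    "night_index",
    "recording_path",
    "hypnogram_path",
    "disposition",
    "actigraphy_tst_min",
)


class EdfParseError(ValueError):
    """Malformed EDF content; carries the byte offset of the offending field."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as 16-bit EDF with physical units µV.

    Each data record spans 1 s; a trailing partial second is zero-padded.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_sig = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs)) if recording.n_samples else 0

    data = np.zeros((n_sig, n_records * fs))
    data[:, : recording.n_samples] = recording.samples

    # Per-channel symmetric physical range; 1.0 floor avoids zero-width ranges.
    pmax = np.maximum(np.abs(data).max(axis=1), 1.0)
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None]).astype(np.int64) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    st = recording.start_time
    header = io.BytesIO()
    header.write(_pad("0", 8))  # version
    header.write(_pad("X X X X", 80))  # patient id (deidentified)
    header.write(_pad("Startdate X patchsleep", 80))  # recording id
    header.write(_pad(st.strftime("%d.%m.%y"), 8))
    header.write(_pad(st.strftime("%H.%M.%S"), 8))
    header.write(_pad(str(256 * (1 + n_sig)), 8))
    header.write(_pad("", 44))  # reserved
    header.write(_pad(str(n_records), 8))
    header.write(_pad("1", 8))  # record duration (s)
    header.write(_pad(str(n_sig), 4))
    for lab in recording.channel_labels:
        header.write(_pad(lab, 16))
    for _ in range(n_sig):
        header.write(_pad("", 80))  # transducer
    for _ in range(n_sig):
        header.write(_pad("uV", 8))
    for v in pmin:
        header.write(_pad(f"{v:.6g}", 8))
    for v in pmax:
        header.write(_pad(f"{v:.6g}", 8))
    for _ in range(n_sig):
        header.write(_pad(str(dmin), 8))
    for _ in range(n_sig):
        header.write(_pad(str(dmax), 8))
    for _ in range(n_sig):
        header.write(_pad("", 80))  # prefiltering
    for _ in range(n_sig):
        header.write(_pad(str(fs), 8))
    for _ in range(n_sig):
        header.write(_pad("", 32))  # reserved

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        # data records: per record, all samples of signal 0, then signal 1, ...
        interleaved = digital.reshape(n_sig, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(interleaved).tobytes())


def _read_field(buf: bytes, offset: int, width: int, kind: str, what: str):
    raw = buf[offset : offset + width]
    if len(raw) < width:
        raise EdfParseError(f"truncated header while reading {what}", offset)
    text = raw.decode("ascii", errors="replace").strip()
    if kind == "str":
        return text
    try:
        return int(text) if kind == "int" else float(text)
    except ValueError:
        raise EdfParseError(f"cannot parse {what} field {text!r}", offset) from None


def read_edf(path: str | os.PathLike) -> Recording:
    """Read a 16-bit EDF file into a Recording (µV).

    All signals must share one sampling rate (true for patch recordings).
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) == 0:
        raise EdfParseError("empty file", 0)
    if len(buf) < 256:
        raise EdfParseError("file shorter than the 256-byte EDF header", len(buf))
    version = _read_field(buf, 0, 8, "str", "version")
    if version != "0":
        raise EdfParseError(f"unsupported EDF version {version!r}", 0)
    date = _read_field(buf, 168, 8, "str", "start date")
    time = _read_field(buf, 176, 8, "str", "start time")
    n_records = _read_field(buf, 236, 8, "int", "number of records")
    rec_dur = _read_field(buf, 244, 8, "float", "record duration")
    n_sig = _read_field(buf, 252, 4, "int", "signal count")

    off = 256
    labels = [_read_field(buf, off + 16 * i, 16, "str", "label") for i in range(n_sig)]
    off += n_sig * (16 + 80 + 8)  # skip transducer + dimension
    pmin = np.array([_read_field(buf, off + 8 * i, 8, "float", "physical min") for i in range(n_sig)])
    off += n_sig * 8
    pmax = np.array([_read_field(buf, off + 8 * i, 8, "float", "physical max") for i in range(n_sig)])
    off += n_sig * 8
    dmin = np.array([_read_field(buf, off + 8 * i, 8, "int", "digital min") for i in range(n_sig)])
    off += n_sig * 8
    dmax = np.array([_read_field(buf, off + 8 * i, 8, "int", "digital max") for i in range(n_sig)])
    off += n_sig * 8 + n_sig * 80  # skip prefiltering
    nsamp = np.array([_read_field(buf, off + 8 * i, 8, "int", "samples per record") for i in range(n_sig)])
    header_len = 256 * (1 + n_sig)

    if len(set(nsamp.tolist())) != 1:
        raise EdfParseError("signals with differing sampling rates are unsupported", off)
    spr = int(nsamp[0])
    fs = spr / rec_dur

    expected = header_len + 2 * n_records * spr * n_sig
    if len(buf) < expected:
        raise EdfParseError(
            f"data section truncated: expected {expected} bytes, file has {len(buf)}",
            len(buf),
        )
    raw = np.frombuffer(buf, dtype="<i2", offset=header_len, count=n_records * spr * n_sig)
    digital = raw.reshape(n_records, n_sig, spr).transpose(1, 0, 2).reshape(n_sig, -1)
    scale = (pmax - pmin) / (dmax - dmin)
    samples = (digital - dmin[:, None]) * scale[:, None] + pmin[:, None]

    try:
        start = datetime.strptime(f"{date} {time}", "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = datetime(2024, 1, 1)
    return Recording(
        samples=samples,
        fs=fs,
        channel_labels=tuple(labels),
        start_time=start,
        meta={"source": str(path)},
    )


# -- patch app CSV dialect ---------------------------------------------------

_FS_RE = re.compile(r"#\s*fs\s*=\s*([0-9.]+)")


def _read_one_patch_csv(path: Path) -> tuple[float | None, np.ndarray, list[str]]:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        fs = None
        m = _FS_RE.match(first)
        if m:
            fs = float(m.group(1))
            header_line = fh.readline()
        else:
            header_line = first
        header = next(csv.reader([header_line]))
        if not header or header[0].strip() != "sample_index":
            raise ValueError(
                f"{path}: patch CSV must start with a 'sample_index' column, got {header!r}"
            )
        channels = [h.strip() for h in header[1:]]
        body = np.loadtxt(fh, delimiter=",", ndmin=2) if fh.readable() else np.empty((0, 0))
    if body.size == 0:
        raise ValueError(f"{path}: patch CSV contains no samples")
    return fs, body, channels


def read_patch_csv(path_or_prefix: str | os.PathLike, default_fs: float = 250.0) -> Recording:
    """Read one patch CSV file, or every rotation segment matching a prefix.

    Rotation segments are ordered lexicographically (the app's numeric suffix
    ordering) and joined on ``sample_index``. Missing indices are reported in
    ``meta["gaps"]`` as (onset_s, duration_s) spans and filled with NaN.
    """
    p = Path(path_or_prefix)
    if p.is_file():
        files = [p]
    else:
        files = sorted(Path(f) for f in glob.glob(str(p) + "*.csv"))
        if not files:
            raise FileNotFoundError(f"no patch CSV files match {path_or_prefix!r}")

    fs = None
    channels = None
    chunks = []
    for f in files:
        file_fs, body, file_channels = _read_one_patch_csv(f)
        if fs is None:
            fs = file_fs
        if channels is None:
            channels = file_channels
        elif channels != file_channels:
            raise ValueError(f"{f}: channel columns differ across rotation files")
        chunks.append(body)
    fs = fs if fs is not None else default_fs

    table = np.vstack(chunks)
    idx = table[:, 0].astype(np.int64)
    if np.any(np.diff(idx) <= 0):
        bad = int(np.flatnonzero(np.diff(idx) <= 0)[0])
        raise ValueError(
            f"non-monotonic sample_index at row {bad + 1} (index {idx[bad + 1]} after {idx[bad]})"
        )
    idx0 = idx - idx[0]
    n = int(idx0[-1]) + 1
    samples = np.full((len(channels), n), np.nan)
    samples[:, idx0] = table[:, 1:].T

    gaps = []
    jumps = np.flatnonzero(np.diff(idx0) > 1)
    for j in jumps:
        onset = (idx0[j] + 1) / fs
        dur = (idx0[j + 1] - idx0[j] - 1) / fs
        gaps.append((float(onset), float(dur)))

    meta = {"source": str(path_or_prefix), "n_rotation_files": len(files)}
    if gaps:
        meta["gaps"] = gaps
    return Recording(samples=samples, fs=fs, channel_labels=tuple(channels), meta=meta)


def write_patch_csv(recording: Recording, path: str | os.PathLike) -> None:
    """Write a Recording in the patch CSV dialect (single file)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write("sample_index," + ",".join(recording.channel_labels) + "\n")
        idx = np.arange(recording.n_samples)
        table = np.column_stack([idx, recording.samples.T])
        np.savetxt(fh, table, delimiter=",", fmt=["%d"] + ["%.6g"] * recording.n_channels)


# -- hypnograms --------------------------------------------------------------


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    """Read a plain-text hypnogram, one stage token per 30-s epoch per line."""
    stages = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty hypnogram file")
    for i, line in enumerate(lines, start=1):
        tok = line.strip()
        if not tok:
            continue
        if tok not in STAGES:
            raise ValueError(f"{path}: unknown stage token {tok!r} at line {i}")
        stages.append(tok)
    return Hypnogram(stages=stages)


def write_hypnogram(hypnogram: Hypnogram, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(hypnogram.stages) + "\n")


# -- manifests and event tables ----------------------------------------------


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty manifest file")
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    bad = set(df["disposition"]) - set(DISPOSITIONS)
    if bad:
        raise ValueError(f"{path}: unknown dispositions {sorted(bad)}")
    dup = df.duplicated(subset=["participant_id", "night_index"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (participant, night) rows at {list(df.index[dup])}")
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate SleepEvents for CSV export."""
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "onset": e.onset,
                "duration": e.duration,
                "amplitude": e.amplitude,
                "stage": e.stage,
                "channel": e.channel,
            }
            for e in events
        ],
        columns=["kind", "onset", "duration", "amplitude", "stage", "channel"],
    )
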