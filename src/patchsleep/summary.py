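"""Per-night macroarchitecture, per-participant aggregation, retention ledger.

Stage percentages are expressed as a share of total sleep time (TST), never of
time in bed; sleep efficiency is 100·TST/TIB with TIB taken as the full
recording duration (patch-on to patch-off), the device-observable proxy for
time in bed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .containers import Hypnogram, SLEEP_STAGES

#: NightSummary metrics averaged across nights per participant.
NIGHT_METRICS = (
    "tst_min",
    "tib_min",
    "sleep_efficiency",
    "pct_n1",
    "pct_n2",
    "pct_n3",
    "pct_rem",
    "so_density",
    "spindle_density_n2",
    "spindle_density_n3",
    "nrem_rel_delta",
    "snr_db",
)


@dataclass
class NightSummary:
    participant_id: str = ""
    night_index: int = 0
    tst_min: float = math.nan
    tib_min: float = math.nan
    sleep_efficiency: float = math.nan  # %
    pct_n1: float = math.nan  # % of TST
    pct_n2: float = math.nan
    pct_n3: float = math.nan
    pct_rem: float = math.nan
    so_density: float = math.nan  # /min NREM
    spindle_density_n2: float = math.nan  # /min N2
    spindle_density_n3: float = math.nan  # /min N3
    rel_power: dict = field(default_factory=dict)  # per-stage band fractions
    nrem_rel_delta: float = math.nan
    snr_db: float = math.nan


@dataclass
class ParticipantSummary:
    participant_id: str
    group: str
    n_usable_nights: int
    means: dict[str, float]  # metric -> mean over usable nights
    n_defined: dict[str, int] = field(default_factory=dict)  # metric -> nights contributing


def score_night(
    hypnogram: Hypnogram, recording_duration_min: float
) -> dict[str, float]:
    """Macro metrics of one night: TST, TIB, efficiency, stage percentages.

    With zero sleep epochs the stage percentages are undefined (NaN) and
    sleep efficiency is 0.
    """
    if hypnogram.duration_s / 60.0 > recording_duration_min + 0.5:
        raise ValueError(
            f"hypnogram covers {hypnogram.duration_s / 60:.1f} min but the recording "
            f"lasts only {recording_duration_min:.1f} min"
        )
    tst = hypnogram.minutes_of(*SLEEP_STAGES)
    tib = recording_duration_min
    out = {"tst_min": tst, "tib_min": tib}
    out["sleep_efficiency"] = 100.0 * tst / tib if tib > 0 else 0.0
    n_sleep = len(hypnogram.epochs_of(*SLEEP_STAGES))
    for key, stage in (("pct_n1", "N1"), ("pct_n2", "N2"), ("pct_n3", "N3"), ("pct_rem", "REM")):
        if n_sleep == 0:
            out[key] = math.nan
        else:
            out[key] = 100.0 * len(hypnogram.epochs_of(stage)) / n_sleep
    return out


def aggregate_participant(
    nights: list[NightSummary], participant_id: str = "", group: str = ""
) -> ParticipantSummary:
    """Unweighted arithmetic mean of each metric across usable nights.

    A metric undefined for some night (NaN) is skipped for that night; the
    number of contributing nights is recorded per metric.
    """
    if not nights:
        raise ValueError("cannot aggregate an empty night list")
    means: dict[str, float] = {}
    n_defined: dict[str, int] = {}
    for metric in NIGHT_METRICS:
        vals = [getattr(n, metric) for n in nights]
        finite = [v for v in vals if v is not None and np.isfinite(v)]
        n_defined[metric] = len(finite)
        means[metric] = float(np.mean(finite)) if finite else math.nan
    pid = participant_id or (nights[0].participant_id if nights else "")
    return ParticipantSummary(
        participant_id=pid, group=group, n_usable_nights=len(nights),
        means=means, n_defined=n_defined,
    )


def participants_frame(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"participant_id": s.participant_id, "group": s.group,
               "n_usable_nights": s.n_usable_nights}
        row.update(s.means)
        rows.append(row)
    return pd.DataFrame(rows)


# -- retention ledger --------------------------------------------------------

LOSS_CATEGORIES = ("poor_reference_adhesion", "not_worn", "bluetooth")


def fraction_pct(n: int, d: int, decimals: int = 0) -> str:
    """Format n/d as a percentage string with the given decimals (0/0 -> '0')."""
    pct = 0.0 if d == 0 else 100.0 * n / d
    return f"{pct:.{decimals}f}"


@dataclass
class GroupRetention:
    group: str
    # Panel A: participants who contributed zero usable nights
    n_zero_usable_participants: int
    panel_a_scheduled: int
    panel_a_losses: dict[str, int]  # category -> count
    # Panel B: participants with >= 1 usable night
    n_retained_participants: int
    panel_b_scheduled: int
    panel_b_device_use: int
    panel_b_usable: int
    panel_b_losses: dict[str, int]

    def check_conservation(self) -> None:
        a_total = sum(self.panel_a_losses.values())
        if a_total != self.panel_a_scheduled:
            raise AssertionError(
                f"{self.group}: panel A losses {a_total} != scheduled {self.panel_a_scheduled}"
            )
        b_total = self.panel_b_usable + sum(self.panel_b_losses.values())
        if b_total != self.panel_b_scheduled:
            raise AssertionError(
                f"{self.group}: panel B usable+losses {b_total} != scheduled {self.panel_b_scheduled}"
            )
        if not (self.panel_b_usable <= self.panel_b_device_use <= self.panel_b_scheduled):
            raise AssertionError(f"{self.group}: usable <= device-use <= scheduled violated")


def build_retention_ledger(manifest: pd.DataFrame) -> dict[str, GroupRetention]:
    """Data-retention accounting per group, split by participant usability.

    Participants with zero usable nights form Panel A (losses as integer
    percentages of their scheduled nights); participants with at least one
    usable night form Panel B (usable nights as a share of nights with device
    use, to one decimal; loss categories as shares of scheduled nights).
    "Device use" counts every night except those not worn / not connected.
    """
    ledger: dict[str, GroupRetention] = {}
    for group, gdf in manifest.groupby("group", sort=True):
        usable_per = gdf.groupby("participant_id")["disposition"].apply(
            lambda d: (d == "usable").sum()
        )
        zero_ids = set(usable_per[usable_per == 0].index)
        a = gdf[gdf["participant_id"].isin(zero_ids)]
        b = gdf[~gdf["participant_id"].isin(zero_ids)]
        gr = GroupRetention(
            group=str(group),
            n_zero_usable_participants=len(zero_ids),
            panel_a_scheduled=len(a),
            panel_a_losses={c: int((a["disposition"] == c).sum()) for c in LOSS_CATEGORIES},
            n_retained_participants=b["participant_id"].nunique(),
            panel_b_scheduled=len(b),
            panel_b_device_use=int((b["disposition"] != "not_worn").sum()),
            panel_b_usable=int((b["disposition"] == "usable").sum()),
            panel_b_losses={c: int((b["disposition"] == c).sum()) for c in LOSS_CATEGORIES},
        )
        gr.check_conservation()
        ledger[str(group)] = gr
    return ledger


def format_retention_ledger(ledger: dict[str, GroupRetention]) -> str:
    """Human-readable two-panel retention table."""
    lines = ["Sleep EEG data retention", ""]
    groups = list(ledger)
    header = "measure" + "".join(f"\t{g}" for g in groups)
    lines.append("Panel A: participants with 0 usable nights")
    lines.append(header)
    for cat in LOSS_CATEGORIES:
        row = cat
        for g in groups:
            gr = ledger[g]
            n, d = gr.panel_a_losses[cat], gr.panel_a_scheduled
            row += f"\t{n}/{d} ({fraction_pct(n, d, 0)})"
        lines.append(row)
    lines.append("")
    lines.append("Panel B: participants with >= 1 usable night")
    lines.append(header)
    row = "usable nights (of nights with device use)"
    for g in groups:
        gr = ledger[g]
        row += f"\t{gr.panel_b_usable}/{gr.panel_b_device_use} " \
               f"({fraction_pct(gr.panel_b_usable, gr.panel_b_device_use, 1)})"
    lines.append(row)
    for cat in LOSS_CATEGORIES:
        row = f"{cat} (of scheduled nights)"
        for g in groups:
            gr = ledger[g]
            n, d = gr.panel_b_losses[cat], gr.panel_b_scheduled
            row += f"\t{n}/{d} ({fraction_pct(n, d, 1)})"
        lines.append(row)
    return "\n".join(lines)


def ledger_frame(ledger: dict[str, GroupRetention]) -> pd.DataFrame:
    rows = []
    for g, gr in ledger.items():
        for f in fields(gr):
            val = getattr(gr, f.name)
            if isinstance(val, dict):
                for k, v in val.items():
                    rows.append({"group": g, "measure": f"{f.name}.{k}", "value": v})
            elif f.name != "group":
                rows.append({"group": g, "measure": f.name, "value": val})
    return pd.DataFrame(rows)
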