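#!/usr/bin/env python
"""Run the full per-night pipeline over the simulated cohort.

For every manifest night: QC filters, retention gate, downsampling, covariance
artifact mask, hypnogram ingestion, slow-oscillation and spindle detection,
stage-wise spectral summaries, macro metrics; then per-participant averaging
and the two-panel retention ledger. Writes participants.csv,
group_comparison.csv, retention_ledger.{csv,txt} under results/.
"""

from pathlib import Path

from patchsleep.pipeline import RunConfig, run_cohort
from patchsleep.summary import format_retention_ledger

ROOT = Path(__file__).resolve().parents[1]
MANIFEST = ROOT / "scratch" / "cohort" / "manifest.csv"
OUT = ROOT / "results"

if __name__ == "__main__":
    if not MANIFEST.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    res = run_cohort(MANIFEST, RunConfig(), out_dir=OUT)
    usable = [r for r in res["night_results"] if r.summary is not None]
    print(f"processed {len(res['night_results'])} nights; {len(usable)} usable")
    print(f"participants with >= 1 usable night: {len(res['participants'])}")
    print()
    print(format_retention_ledger(res["ledger"]))
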