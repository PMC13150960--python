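#!/usr/bin/env python
"""Young-vs-old comparison of every per-participant sleep measure.

Reads results/participants.csv and prints the comparison table in the usual
layout: group means (SD), centered Mann-Whitney U, two-sided p, rank-biserial
effect size with its 95% Fisher-z CI. Expected pattern at the default
generator contrasts: lower N3% and spindle density in the old group, higher
N2%, with the N3 and spindle rows significant.
"""

from pathlib import Path

import pandas as pd

from patchsleep.pipeline import COMPARISON_MEASURES
from patchsleep.stats import compare_groups, comparison_frame, format_comparison_table

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    pf = pd.read_csv(ROOT / "results" / "participants.csv")
    measures = [m for m in COMPARISON_MEASURES if m in pf.columns]
    rows = compare_groups(pf, measures)
    print(format_comparison_table(rows))
    comparison_frame(rows).to_csv(ROOT / "results" / "group_comparison.csv", index=False)
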