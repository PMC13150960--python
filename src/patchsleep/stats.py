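"""Two-group comparisons: centered Mann-Whitney U, rank-biserial r, Fisher-z CI.

Conventions: U counts pairs where the first group's value exceeds the second's,
with ties half-counted; the reported statistic is centered, U_c = U − n1·n2/2,
so it is positive when the first group tends larger and can take half-integer
values under ties. The rank-biserial correlation is r = U_c / (n1·n2/2). Its
confidence interval uses the Fisher z-transform with standard error
sqrt((n1+n2+1)/(3·n1·n2)), the classical large-sample SE of a rank
correlation, back-transformed with tanh.

P-values are exact (distribution of U under exchangeability) when there are no
ties and both groups have at most 25 observations; otherwise a normal
approximation with midranks and tie-corrected variance, without continuity
correction, is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss


@dataclass
class MannWhitneyResult:
    u: float  # raw U for the first group
    u_centered: float  # U - n1*n2/2
    p_value: float
    method: str  # "exact" | "asymptotic"


@dataclass
class GroupComparison:
    measure: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    median1: float
    iqr1: tuple[float, float]
    median2: float
    iqr2: tuple[float, float]
    u_centered: float
    p_value: float
    r_rank_biserial: float
    ci_low: float
    ci_high: float
    significant: bool


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + ½·#ties, via midranks."""
    n1 = x.size
    combined = np.concatenate([x, y])
    ranks = ss.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney_centered(x, y, exact_max_n: int = 25) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test reporting the centered statistic.

    Positive ``u_centered`` means values in ``x`` tend to exceed those in ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2

    if not has_ties and n1 <= exact_max_n and n2 <= exact_max_n:
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p, method = float(res.pvalue), "exact"
    else:
        # normal approximation, midranks, tie-corrected variance, no continuity
        n = n1 + n2
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - n1 * n2 / 2.0) / math.sqrt(var)
            p = float(2 * ss.norm.sf(abs(z)))
        method = "asymptotic"
    return MannWhitneyResult(u=u, u_centered=u - n1 * n2 / 2.0, p_value=min(p, 1.0), method=method)


def rank_biserial(u_centered: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = U_c / (n1·n2/2), in [−1, 1]."""
    half = n1 * n2 / 2.0
    if abs(u_centered) > half + 1e-9:
        raise ValueError(f"|u_centered|={abs(u_centered)} exceeds n1*n2/2={half}")
    return u_centered / half


def rank_biserial_ci(
    r: float, n1: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Fisher-z confidence interval for the rank-biserial correlation."""
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: degenerate interval returned", stacklevel=2)
        return (r, r)
    z = math.atanh(r)
    se = math.sqrt((n1 + n2 + 1) / (3.0 * n1 * n2))
    half = ss.norm.ppf(0.5 + level / 2.0) * se
    return (math.tanh(z - half), math.tanh(z + half))


def _iqr(v: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(v, 25)), float(np.percentile(v, 75)))


def compare_groups(
    participants: pd.DataFrame,
    measures: list[str],
    group_col: str = "group",
    group_a: str = "young",
    group_b: str = "old",
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """One comparison row per measure between two participant groups.

    ``u_centered`` (and r) are positive when ``group_a`` exceeds ``group_b``.
    Rows are computed on participants with a defined (non-NaN) value; no
    multiple-testing correction is applied across rows.
    """
    ga = participants[participants[group_col] == group_a]
    gb = participants[participants[group_col] == group_b]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError(f"both groups must be non-empty ({group_a}: {len(ga)}, {group_b}: {len(gb)})")
    rows = []
    for measure in measures:
        x = ga[measure].dropna().to_numpy(dtype=float)
        y = gb[measure].dropna().to_numpy(dtype=float)
        if x.size == 0 or y.size == 0:
            continue
        mw = mann_whitney_centered(x, y)
        r = rank_biserial(mw.u_centered, x.size, y.size)
        lo, hi = rank_biserial_ci(r, x.size, y.size) if abs(r) < 1 else (r, r)
        rows.append(
            GroupComparison(
                measure=measure, n1=x.size, n2=y.size,
                mean1=float(x.mean()), sd1=float(x.std(ddof=1)) if x.size > 1 else 0.0,
                mean2=float(y.mean()), sd2=float(y.std(ddof=1)) if y.size > 1 else 0.0,
                median1=float(np.median(x)), iqr1=_iqr(x),
                median2=float(np.median(y)), iqr2=_iqr(y),
                u_centered=mw.u_centered, p_value=mw.p_value,
                r_rank_biserial=r, ci_low=lo, ci_high=hi,
                significant=mw.p_value < alpha,
            )
        )
    return rows


def comparison_frame(rows: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": c.measure, "n_young": c.n1, "n_old": c.n2,
                "young_mean": c.mean1, "young_sd": c.sd1,
                "old_mean": c.mean2, "old_sd": c.sd2,
                "young_median": c.median1, "young_q25": c.iqr1[0], "young_q75": c.iqr1[1],
                "old_median": c.median2, "old_q25": c.iqr2[0], "old_q75": c.iqr2[1],
                "u_centered": c.u_centered, "p_value": c.p_value,
                "r": c.r_rank_biserial, "ci_low": c.ci_low, "ci_high": c.ci_high,
                "significant": c.significant,
            }
            for c in rows
        ]
    )


def format_comparison_table(rows: list[GroupComparison]) -> str:
    """Aligned text table in the usual column order (means, medians, U, p, r, CI)."""
    lines = [
        f"{'measure':<22}{'young mean (SD)':>20}{'old mean (SD)':>20}"
        f"{'U_c':>8}{'p':>8}{'r (95% CI)':>28}"
    ]
    for c in rows:
        star = "*" if c.significant else ""
        lines.append(
            f"{c.measure:<22}"
            f"{c.mean1:>12.2f} ({c.sd1:.2f}){c.mean2:>12.2f} ({c.sd2:.2f})"
            f"{c.u_centered:>8.1f}{c.p_value:>8.3f}"
            f"{c.r_rank_biserial:>9.3f} ({c.ci_low:.3f} to {c.ci_high:.3f}){star}"
        )
    lines.append("No multiple-testing correction applied across rows; * p < 0.05.")
    return "\n".join(lines)
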