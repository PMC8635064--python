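"""Group-comparison and association statistics for cohort description.

Effect sizes and t-tests operate on *summary* statistics (n, mean, sample
SD) so printed demographic tables can be checked without participant-level
data; the nonparametric tests and correlations operate on raw vectors.
Pooled-variance Student's t (not Welch) and pooled-SD Cohen's d are used, by
the reporting convention group 1 = women.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float  # sample SD

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("negative SD")


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    num = (g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2
    return math.sqrt(num / (g1.n + g2.n - 2))


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> float:
    """Pooled-SD standardized mean difference (mean1 - mean2) / s_pooled."""
    sp = _pooled_sd(g1, g2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    return (g1.mean - g2.mean) / sp


def two_sample_t(g1: GroupSummary, g2: GroupSummary) -> Dict[str, float]:
    """Pooled-variance Student's t from group summaries; two-sided p."""
    sp = _pooled_sd(g1, g2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    df = g1.n + g2.n - 2
    t = (g1.mean - g2.mean) / (sp * math.sqrt(1 / g1.n + 1 / g2.n))
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": t, "df": float(df), "p": float(p)}


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """U statistic for the first sample (midrank ties), p by the
    tie-corrected normal approximation."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Spearman rank correlation (Pearson on midranks), p by t approximation.

    A constant input leaves rho undefined: NaN is returned with the flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return {"rho": float("nan"), "p": float("nan"), "undefined": 1.0}
    res = stats.spearmanr(x, y)
    return {"rho": float(res.statistic), "p": float(res.pvalue),
            "undefined": 0.0}


def chi_square_2x2(table: Sequence[Sequence[float]]) -> Dict[str, float]:
    """Chi-square test of independence on a 2x2 count table, df = 1.

    Continuity correction is off by default (documented convention); a zero
    row or column marginal raises.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return {"chi2": float(chi2), "df": float(df), "p": float(p)}
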