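"""Group-comparison statistics for the multimodal readouts.

Mann-Whitney U (exact for small pooled samples, tie-corrected normal
approximation otherwise) for AFM and coherency comparisons; one-way ANOVA
with Bonferroni-adjusted pairwise t-tests for viscosity and SIMS intensity
comparisons. Two-sided throughout; 0.05 is the conventional significance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MannWhitneyResult", "AnovaResult", "mann_whitney", "anova_bonferroni"]

#: pooled-sample size at or below which the exact U distribution is used
EXACT_LIMIT = 20


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # raw and Bonferroni-adjusted p per group pair


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the pooled sample is small
    (``n_a + n_b <= 20``) and ties are absent; otherwise the normal
    approximation with tie correction. ``u_statistic`` is the U of the first
    sample; swapping the samples maps U to ``n_a * n_b - U`` with the same p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u_statistic=float(res.statistic),
                             p_value=float(res.pvalue), method=method)


def anova_bonferroni(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise t-tests.

    The omnibus F compares all groups; every pair is then tested with a
    two-sample t-test and the raw p multiplied by the number of pairs,
    capped at 1. Identical groups give F = 0, p = 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for g in names:
        arr = np.asarray(groups[g], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {g!r} contains non-finite values")
        arrays.append(arr)

    if all(np.allclose(arr, arrays[0], atol=0) and arr.size == arrays[0].size
           for arr in arrays) and all(np.ptp(arr) == 0 for arr in arrays):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0

    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.ptp(arrays[i]) == 0 and np.ptp(arrays[j]) == 0 and \
                    arrays[i][0] == arrays[j][0]:
                raw = 1.0
            else:
                raw = float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
                if np.isnan(raw):
                    raw = 1.0
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "p_raw": raw,
                "p_adjusted": min(raw * n_pairs, 1.0),
            })
    return AnovaResult(f_statistic=float(f_stat), p_value=float(p),
                       pairwise=pd.DataFrame(rows))
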