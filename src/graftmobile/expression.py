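"""Count normalization and a simplified differential-expression rule.

Size factors follow the median-of-ratios scheme: each sample's factor is the
median, over genes detected in every sample, of its counts divided by the
gene's geometric mean across samples.  Differential expression is a
deliberately simple, self-contained decision rule — log2 fold change of
pseudocounted group means plus a two-sided Welch t-test on log counts — with
the published cutoff semantics |log2FC| > 1 and P < 0.05.  It is a documented
stand-in, not a reimplementation of a shrinkage-based DE framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DECall:
    gene: str
    log2fc: float
    p_value: float
    status: str  # "Up" | "Down" | "NS"


def normalize_median_of_ratios(
    count_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors and the normalized matrix.

    Rows are genes, columns are samples, entries nonnegative integer counts.
    Raises if fewer than two samples, or if no gene has positive counts in
    every sample (geometric means would all be zero).
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    counts = count_matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with positive counts in every sample")
    log_counts = np.log(counts[all_positive])
    log_geo_mean = log_counts.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(log_counts - log_geo_mean, axis=0))
    factors = pd.Series(size_factors, index=count_matrix.columns, name="size_factor")
    return count_matrix / factors, factors


def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    pseudocount: float = 1.0,
    log2fc_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene fold change, Welch p-value and Up/Down/NS status.

    ``group_a`` (control) and ``group_b`` (treatment) are normalized count
    matrices (genes x samples) sharing the same gene index.  log2fc =
    log2((mean_b + pseudocount) / (mean_a + pseudocount)); the p-value is a
    two-sided unequal-variance t-test on log2(count + 1).  Groups with fewer
    than two samples yield NaN p-values and NS status, with a warning.
    """
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share the same gene index")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    if a.shape[1] < 2 or b.shape[1] < 2:
        warnings.warn(
            "fewer than two samples per group: p-values undefined, all NS",
            stacklevel=2,
        )
        p = np.full(len(log2fc), np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(
                np.log2(b + 1.0), np.log2(a + 1.0), axis=1, equal_var=False
            )

    status = np.where(
        (log2fc > log2fc_cutoff) & (p < alpha),
        "Up",
        np.where((log2fc < -log2fc_cutoff) & (p < alpha), "Down", "NS"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "status": status}, index=group_a.index
    )
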