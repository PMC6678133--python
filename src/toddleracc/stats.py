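"""Descriptive and comparative statistics: per-behavior count summaries,
Mann-Whitney comparisons, and the d' sensitivity-index feature ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .features import FEATURE_NAMES

__all__ = [
    "summarize_counts",
    "mann_whitney",
    "dprime",
    "rank_features",
]


def summarize_counts(rates: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of per-participant count rates.

    ``rates`` is the tidy output of
    :func:`toddleracc.counts.behavior_count_rate` concatenated over
    participants (columns participant, behavior, site, measure, rate).
    Returns one row per (site, measure, behavior) with ``median``,
    ``q1``, ``q3`` (linear-interpolation quartiles) and ``n``
    participants.
    """
    cols = ["site", "measure", "behavior", "median", "q1", "q3", "n"]
    if rates.empty:
        return pd.DataFrame(columns=cols)
    records = []
    for (site, measure, behavior), grp in rates.groupby(
        ["site", "measure", "behavior"], sort=True, dropna=False
    ):
        vals = grp["rate"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        records.append({
            "site": site, "measure": measure, "behavior": behavior,
            "median": med, "q1": q1, "q3": q3, "n": len(vals),
        })
    return pd.DataFrame.from_records(records, columns=cols)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U of group A, p).

    Uses the exact U distribution when the combined sample is small
    (n_A + n_B <= 20) and tie-free, and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def dprime(values_a, values_b) -> float:
    """Sensitivity index d' between two empirical distributions.

    d' = |mean(A) - mean(B)| / sqrt((var(A) + var(B)) / 2) with sample
    (ddof=1) variances.  Degenerate zero-variance groups: equal means
    give 0; unequal means give +inf.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = abs(a.mean() - b.mean())
    pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(pooled))


@dataclass(frozen=True)
class DPrimeRanking:
    """All features scored by d' between two groups, sorted descending."""

    ranking: pd.DataFrame  # columns: feature, dprime
    group_a: str
    group_b: str

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.ranking.head(k).reset_index(drop=True)


def rank_features(
    feature_table: pd.DataFrame,
    binary_labels,
    feature_columns: tuple[str, ...] = FEATURE_NAMES,
) -> DPrimeRanking:
    """Score every feature by d' between the two label groups.

    ``binary_labels`` is a length-n sequence with exactly two distinct
    values (e.g. "carried"/"ambulation").  Sorted by descending d'; ties
    broken alphabetically by feature name.
    """
    labels = np.asarray(binary_labels)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask_a = labels == classes[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each class needs at least 2 windows")

    rows = []
    for name in feature_columns:
        vals = feature_table[name].to_numpy(dtype=float)
        rows.append({"feature": name, "dprime": dprime(vals[mask_a], vals[~mask_a])})
    df = pd.DataFrame(rows).sort_values(
        ["dprime", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return DPrimeRanking(ranking=df, group_a=str(classes[0]), group_b=str(classes[1]))
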