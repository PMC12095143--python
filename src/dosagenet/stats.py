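"""Batch statistics: median splits, Wilcoxon rank-sum, Pearson correlation.

These back the ensemble-level analyses: prescriptions are split at the
median of an output indicator (DeDT or DePy) into "low"/"high" groups —
or at the median drug count into "less"/"more" — and the input
indicators (Dedis, DeSD) are compared between groups with the two-sided
Wilcoxon rank-sum test.  Pearson correlation quantifies the linear
relationships (Dedis vs DeSD; drug count vs SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "median_split",
    "wilcoxon_rank_sum",
    "pearson_cor",
    "batch_report",
]

# Below this combined sample size (and with no ties) the exact
# permutation null is enumerated; above it the normal approximation with
# tie and continuity corrections is used.
EXACT_SWITCH_N = 12


@dataclass
class GroupedSample:
    """A median split: per-item labels, values and the cutoff used."""

    labels: list[str]
    values: list[float]
    split_value: float
    low_label: str = "low"
    high_label: str = "high"

    def group(self, label: str) -> list[float]:
        return [v for l, v in zip(self.labels, self.values) if l == label]

    @property
    def low(self) -> list[float]:
        return self.group(self.low_label)

    @property
    def high(self) -> list[float]:
        return self.group(self.high_label)


def median_split(
    split_var: Sequence[float],
    values: Sequence[float],
    low_label: str = "low",
    high_label: str = "high",
) -> GroupedSample:
    """Split items at the median of ``split_var``.

    Items strictly above the median are labeled high; items at or below
    it are labeled low.  The median is the midpoint of the central order
    statistics for even n.
    """
    split_var = np.asarray(split_var, dtype=float)
    values = np.asarray(values, dtype=float)
    if split_var.shape != values.shape:
        raise ValueError("split_var and values must have equal length")
    if split_var.size < 2:
        raise ValueError("need at least 2 items to split")
    med = float(np.median(split_var))
    labels = [high_label if s > med else low_label for s in split_var]
    return GroupedSample(
        labels=labels,
        values=[float(v) for v in values],
        split_value=med,
        low_label=low_label,
        high_label=high_label,
    )


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    continuity: bool = True,
    exact_switch_n: int = EXACT_SWITCH_N,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(W, p)`` where W is the rank-sum statistic of the first
    sample (midranks for ties).  The exact permutation distribution is
    used when the combined size is at most ``exact_switch_n`` and there
    are no ties; otherwise the normal approximation with tie correction
    (and continuity correction unless disabled) applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= exact_switch_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    # rank-sum statistic W = U + n_a(n_a+1)/2
    w = float(res.statistic + a.size * (a.size + 1) / 2)
    return w, float(res.pvalue)


def pearson_cor(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _group_comparison(split_var, values, comparison: str,
                      low: str = "low", high: str = "high") -> dict:
    """Median-split ``split_var`` and Wilcoxon-compare ``values`` between groups."""
    grouped = median_split(split_var, values, low, high)
    entry: dict = {
        "comparison": comparison,
        "median_cutoff": grouped.split_value,
        "group_sizes": {low: len(grouped.low), high: len(grouped.high)},
    }
    try:
        w, p = wilcoxon_rank_sum(grouped.low, grouped.high)
        entry.update(statistic=w, p_value=p)
    except ValueError:
        entry.update(statistic=None, p_value=None,
                     warning="degenerate split: one group empty, test skipped")
    return entry


def batch_report(table) -> dict:
    """Ensemble-level analyses over an indicator table.

    ``table`` is a pandas DataFrame with one row per prescription and
    columns n_drugs, dedis, desd, compound_dedis, compound_desd, dedt,
    depy (depy may be missing/NaN) and optionally total_grams.  For each
    output indicator (dedt, depy) the prescriptions are median-split
    into low/high output-change groups and each input indicator is
    compared between groups (two-sided Wilcoxon).  Prescriptions are
    also split at the median drug count ("less" <= median < "more") to
    compare dosage SD and total dose, and Pearson correlations are
    reported for (dedis, desd) and (n_drugs, desd).
    """
    report: dict = {"n_prescriptions": int(len(table)), "comparisons": []}
    inputs = [c for c in ("dedis", "desd", "compound_dedis", "compound_desd")
              if c in table.columns]
    for out in ("dedt", "depy"):
        if out not in table.columns:
            continue
        sub = table.dropna(subset=[out])
        if len(sub) < 2:
            continue
        for inp in inputs:
            report["comparisons"].append(
                _group_comparison(sub[out].to_numpy(), sub[inp].to_numpy(),
                                  comparison=f"{inp} by {out} group")
            )
    for col in ("desd", "total_grams"):
        if col in table.columns:
            report["comparisons"].append(
                _group_comparison(table["n_drugs"].to_numpy(),
                                  table[col].to_numpy(),
                                  comparison=f"{col} by drug-count group",
                                  low="less", high="more")
            )
    report["correlations"] = {}
    for name, (xc, yc) in {
        "dedis_vs_desd": ("dedis", "desd"),
        "n_drugs_vs_desd": ("n_drugs", "desd"),
    }.items():
        try:
            r, p = pearson_cor(table[xc].to_numpy(), table[yc].to_numpy())
            report["correlations"][name] = {"r": r, "p_value": p}
        except ValueError as exc:
            report["correlations"][name] = {"r": None, "p_value": None,
                                            "warning": str(exc)}
    return report
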