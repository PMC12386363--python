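"""Group-level nonparametric statistics: median [Q1; Q3] summaries and Kruskal-Wallis.

Treatment groups (e.g. intact vs acute-agonist vs chronic-agonist cultures)
are compared per metric with the Kruskal-Wallis rank test; the experimental
unit is one recorded field of view. Dispersion is reported as the
interquartile range with linear-interpolation (type-7) quantiles, formatted
"M [Q1; Q3]". Dunn's pairwise test with Holm adjustment is provided as an
extension beyond the omnibus comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Summary",
    "ComparisonResult",
    "summarize",
    "summarize_groups",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_metric_table",
]


@dataclass(frozen=True)
class Summary:
    """Median and interquartile range of one sample."""

    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def formatted(self, digits: int = 2) -> str:
        return (f"{self.median:.{digits}f} "
                f"[{self.q1:.{digits}f}; {self.q3:.{digits}f}]")


def summarize(values: Sequence[float]) -> Summary:
    """Median [Q1; Q3] with linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return Summary(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, Summary]:
    return {name: summarize(vals) for name, vals in groups.items()}


@dataclass
class ComparisonResult:
    """Kruskal-Wallis comparison of one metric across treatment groups."""

    metric_name: str
    summaries: dict[str, Summary]
    h_statistic: float
    p_value: float
    alpha: float = 0.05
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def kruskal_wallis(groups: Mapping[str, Sequence[float]],
                   metric_name: str = "", alpha: float = 0.05,
                   posthoc: bool = False) -> ComparisonResult:
    """Kruskal-Wallis H on midranks with tie correction; chi-square p-value.

    Requires at least two groups with n >= 2 each. If every value across all
    groups is identical the statistic is defined as H = 0, p = 1.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    result = ComparisonResult(
        metric_name=metric_name,
        summaries={k: summarize(a) for k, a in zip(names, arrays)},
        h_statistic=float(h), p_value=float(p), alpha=alpha,
    )
    if posthoc:
        result.pairwise = dunn_posthoc(groups)
    return result


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled midranks with Holm adjustment.

    z_ab = (Rbar_a - Rbar_b) / sqrt(S * (1/n_a + 1/n_b)) with
    S = (N (N+1) / 12) * (1 - sum(t^3 - t) / (N^3 - N)) for tie groups of
    size t. Provided as an extension; the omnibus decision comes from the
    Kruskal-Wallis test.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n_total ** 3 - n_total)
    s = (n_total * (n_total + 1) / 12.0) * (1.0 - tie_term)
    raw: list[float] = []
    pairs: list[tuple[str, str]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(s * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            raw.append(2.0 * stats.norm.sf(abs(z)))
            pairs.append((names[i], names[j]))
    # Holm step-down adjustment
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * raw[idx])
        adj[idx] = min(1.0, running)
    return {pair: float(p) for pair, p in zip(pairs, adj)}


def compare_metric_table(table: pd.DataFrame, group_col: str = "group",
                         value_col: str = "value", metric_col: str = "metric",
                         alpha: float = 0.05,
                         posthoc: bool = False) -> list[ComparisonResult]:
    """Run one Kruskal-Wallis comparison per metric of a tidy samples table.

    Groups with fewer than 2 finite samples for a metric are dropped from that
    metric's comparison; metrics with fewer than 2 remaining groups are
    skipped.
    """
    results = []
    for metric, sub in table.groupby(metric_col, sort=True):
        groups = {}
        for g, gs in sub.groupby(group_col, sort=True):
            vals = gs[value_col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2:
                groups[str(g)] = vals
        if len(groups) >= 2:
            results.append(kruskal_wallis(groups, metric_name=str(metric),
                                          alpha=alpha, posthoc=posthoc))
    return results
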