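"""Nonparametric comparisons of metrics across resistance levels.

Two-sided Mann–Whitney U tests between every unordered pair of condition
levels, with the exact null distribution when both samples are small and
tie-free and the tie-corrected, continuity-corrected normal approximation
otherwise.  No multiple-comparison correction is applied by default (a Holm
option exists); significance is flagged at alpha = 0.05.  A Wilcoxon
signed-rank variant is available for strictly paired designs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "pairwise_tests",
    "results_to_frame",
    "ALPHA",
    "DEFAULT_EXACT_MAX_N",
]

ALPHA = 0.05
DEFAULT_EXACT_MAX_N = 20


@dataclass
class ComparisonResult:
    metric_name: str
    condition_a: object
    condition_b: object
    U: float
    p_value: float
    n_a: int
    n_b: int
    significant_at_0_05: bool
    method: str = "exact"


def mann_whitney_u(
    x,
    y,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    metric_name: str = "",
    condition_a="a",
    condition_b="b",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    Uses exact null enumeration when both samples have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    ``U`` is the statistic of the first sample (0 <= U <= n_a * n_b).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and x.size <= exact_max_n and y.size <= exact_max_n
    method = "exact" if use_exact else "asymptotic"
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = min(1.0, float(res.pvalue))
    return ComparisonResult(
        metric_name=metric_name,
        condition_a=condition_a,
        condition_b=condition_b,
        U=float(res.statistic),
        p_value=p,
        n_a=int(x.size),
        n_b=int(y.size),
        significant_at_0_05=p < ALPHA,
        method=method,
    )


def _holm(results: list[ComparisonResult]) -> None:
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * results[idx].p_value)
        running = max(running, adj)
        results[idx].p_value = running
        results[idx].significant_at_0_05 = running < ALPHA


def pairwise_tests(
    metric_table: pd.DataFrame,
    metric_name: str,
    value_col: str = "value",
    condition_col: str = "condition",
    paired: bool = False,
    holm: bool = False,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> list[ComparisonResult]:
    """Test every unordered pair of condition levels for one metric.

    ``metric_table`` is tidy (one row per observation).  Conditions with
    fewer than 2 observations are skipped with a warning.  With
    ``paired=True`` a Wilcoxon signed-rank test on aligned observations is
    used instead of the unpaired rank-sum test.
    """
    table = metric_table
    if "metric" in table.columns:
        table = table[table["metric"] == metric_name]
    groups: dict[object, np.ndarray] = {}
    for cond, sub in table.groupby(condition_col, sort=True):
        vals = sub[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(
                f"condition {cond!r} has {vals.size} value(s); skipped", stacklevel=2
            )
            continue
        groups[cond] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 condition levels with >= 2 values")
    results = []
    for a, b in combinations(sorted(groups), 2):
        if paired:
            xa, xb = groups[a], groups[b]
            if xa.size != xb.size:
                raise ValueError("paired tests require equal group sizes")
            res = sstats.wilcoxon(xa, xb, alternative="two-sided")
            p = min(1.0, float(res.pvalue))
            results.append(
                ComparisonResult(
                    metric_name=metric_name,
                    condition_a=a,
                    condition_b=b,
                    U=float(res.statistic),
                    p_value=p,
                    n_a=int(xa.size),
                    n_b=int(xb.size),
                    significant_at_0_05=p < ALPHA,
                    method="wilcoxon",
                )
            )
        else:
            results.append(
                mann_whitney_u(
                    groups[a],
                    groups[b],
                    exact_max_n=exact_max_n,
                    metric_name=metric_name,
                    condition_a=a,
                    condition_b=b,
                )
            )
    if holm:
        _holm(results)
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy results table with the '*' significance marker convention."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric_name,
                "condition_a": r.condition_a,
                "condition_b": r.condition_b,
                "U": r.U,
                "p_value": r.p_value,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "method": r.method,
                "significant": "*" if r.significant_at_0_05 else "",
            }
        )
    return pd.DataFrame(rows)
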