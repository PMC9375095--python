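"""Nonparametric group comparisons and box-plot summaries for per-cell data.

Implements the two statistical procedures used downstream of per-cell RCP
counts: the two-sided Wilcoxon–Mann–Whitney rank-sum test for two groups
(exact enumeration for small samples, tie- and continuity-corrected normal
approximation for large ones) and Kruskal–Wallis with Dunn's pairwise
post-hoc z tests under Bonferroni correction for three or more groups; plus
the Tukey box-plot summary (median, quartiles, 1.5 IQR whiskers, outliers).

Quartiles follow the linear-interpolation convention between order
statistics. The exact rank-sum null distribution is computed by a
generating-function dynamic program over doubled mid-ranks, so ties are
handled exactly; the two-sided exact p is twice the smaller tail probability,
capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "KruskalDunnResult",
    "BoxSummary",
    "rank_sum_test",
    "kw_dunn",
    "box_summary",
]


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    method: str  # "exact" or "approx"


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    comparisons: list[dict]  # per pair: groups, z, p_raw, p_adj


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _exact_ranksum_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Exact two-sided p for the rank sum of a size-``n`` subset.

    Enumerates the permutation distribution of the rank sum over all
    equally likely subsets via a subset-sum dynamic program on doubled
    mid-ranks (integers even with ties). Counts stay below 2**53 for the
    group sizes where the exact path is used, so float64 arithmetic is exact.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    # f[k, s] = number of size-k subsets with doubled rank sum s
    f = np.zeros((n + 1, total + 1))
    f[0, 0] = 1.0
    for r in doubled:
        # simultaneous update: each item may be used at most once
        f[1 : n + 1, r:] += f[0:n, : total + 1 - r].copy()
    n_subsets = f[n].sum()
    probs = f[n] / n_subsets
    w2 = int(round(2 * w_obs))
    lower = probs[: w2 + 1].sum()
    upper = probs[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum_test(
    x,
    y,
    method: str = "auto",
    exact_threshold: int = 20,
    continuity: bool = True,
) -> RankSumResult:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test with mid-ranks for ties.

    ``method="auto"`` enumerates the exact permutation distribution when both
    groups have fewer than ``exact_threshold`` observations, and otherwise
    uses the normal approximation with tie correction and (optionally) a
    0.5 continuity correction. The statistic reported is the Mann–Whitney U
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2

    if method == "auto":
        method = "exact" if max(n, m) < exact_threshold else "approx"
    if method == "exact":
        p = _exact_ranksum_p(ranks, n, w)
        return RankSumResult(statistic=u, p_value=p, method="exact")
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")

    N = n + m
    mu = n * m / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (N * (N - 1))
    var = n * m / 12 * ((N + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return RankSumResult(statistic=u, p_value=1.0, method="approx")
    diff = u - mu
    if continuity:
        diff = np.sign(diff) * max(abs(diff) - 0.5, 0.0)
    z = diff / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankSumResult(statistic=u, p_value=p, method="approx")


def kw_dunn(groups, labels=None) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie-corrected) plus Dunn's pairwise post-hoc tests.

    ``groups`` is a sequence of >= 3 non-empty samples. Dunn z statistics use
    pooled mid-ranks with tie correction; two-sided p values are
    Bonferroni-adjusted over all pairwise comparisons
    (``p_adj = min(1, p_raw * n_pairs)``). For two groups use
    :func:`rank_sum_test` instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kw_dunn requires >= 3 groups; use rank_sum_test for two")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = sps.kruskal(*groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = (counts**3 - counts).sum()
    base_var = N * (N + 1) / 12 - tie_sum / (12 * (N - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    comparisons = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            var = base_var * (1 / sizes[i] + 1 / sizes[j])
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
            p_raw = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
            comparisons.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "z": float(z),
                    "p_raw": p_raw,
                    "p_adj": float(min(1.0, p_raw * n_pairs)),
                }
            )
    return KruskalDunnResult(h_statistic=float(h), p_value=float(p_kw), comparisons=comparisons)


def box_summary(sample) -> BoxSummary:
    """Tukey box-plot summary of one sample.

    Median and quartiles by linear interpolation between order statistics;
    whiskers at the most extreme observations within 1.5 IQR of the
    quartiles; points beyond the whiskers listed as outliers.
    """
    data = np.asarray(sample, dtype=float)
    if data.size == 0:
        raise ValueError("sample must be non-empty")
    q1, med, q3 = np.percentile(data, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = data[(data >= lo_fence) & (data <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(data[(data < lo_fence) | (data > hi_fence)]))
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
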